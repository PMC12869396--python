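# Methods

## Model and inference

The agent's generative model treats sensor detections as independent
Bernoulli variables with probability ℓ(ϕᵢ), the stationary detection
likelihood of the plume at the sensor's absolute position ϕᵢ = ξ + δᵢ.
Inference maximizes the log-posterior over candidate centers ξ on the
lattice of the likelihood field restricted to a uniform prior rectangle.
Numerical choices:

- probabilities are clamped to [10⁻⁶, 1 − 10⁻⁶] before taking logs (the
  model itself produces exact 0s upwind and exact 1s near the source, and
  empirical maps produce both at finite sample size);
- perceived offsets are rounded to whole lattice steps, so every candidate
  evaluation is a table lookup; sensors falling off the grid read the
  nearest edge node;
- ties in the argmax break to the smallest x̂, then the smallest ŷ
  (candidates are scanned in (x, y)-lexicographic order), making every
  estimate deterministic;
- an exhaustive per-candidate evaluation is kept in the test suite as an
  oracle: the production argmax (which aggregates sensors sharing a
  lattice offset into counts) must match it bit-exactly.

The conical likelihood exceeds 1 for ϕₓ < λ; values are clamped to [0, 1]
and the default domain starts at x = λ, so the clamped region is not part
of any fit or scan. The isotropic control uses min(1, (r/λ)^(−δ)): the
same centerline statistics with the directional geometry removed, which is
exactly the contrast the isotropic experiments need.

## Fitting the plume model

Away from saturation the model is log-linear in the predictor
[1, ln ϕₓ, (ϕ_y/ϕₓ)²] with coefficients (δ ln λ, −δ, −1/β²). The fit is a
binomial GLM with log link on the raw per-node detection frequencies over
all non-saturated nodes. Two tempting simplifications are avoided
deliberately: regressing ln ℓ̂ directly is biased at 200 snapshots
(Jensen bias of the log of a small count), and restricting to nodes with
ℓ̂ in a band such as (0.01, 0.99) truncates the far field asymmetrically
(empty cells are discarded, lucky ones kept), biasing the decay exponent.
Both effects were measured at the 2–4 % level — material against a ±5 %
recovery tolerance; the GLM removes them (<1.6 % over ten seeds). A
weighted log-linear regression on the banded nodes (delta-method weights
ℓ/(1−ℓ)) supplies starting values and a fallback if the GLM fails.
Standard errors for (λ, δ, β) follow from the coefficient covariance by
the delta method.

## Surrogate odor data

The DNS odor fields behind the original study are emulated, not
reproduced. The surrogate is a Gaussian copula: a latent unit-variance
Gaussian field with squared-exponential spatial correlation
exp(−d²/(2 ℓ_c²)) (white noise convolved with a Gaussian kernel, with the
discrete kernel norm divided out exactly) and AR(1) temporal correlation,
thresholded node-by-node at the standard-normal quantile of ℓ. This
preserves the likelihood map *exactly* for every correlation setting —
the single property the noise-benefit mechanism requires — while exposing
correlation length and time as free knobs. A strictly positive
raw-concentration proxy c = c₀·exp(s·(g − z)) is derived from the same
latent field (s = 1 by default, giving order-one log-fluctuations as in
intermittent plumes), so thresholding raw at c₀ reproduces the binary
snapshot identically.

What the surrogate does not emulate: DNS spectra, meandering of the
instantaneous plume, near-source widening of the empirical likelihood
relative to the fitted cone, and concentration-dependent patch shapes.
Passing tests therefore demonstrate the geometric mechanism under
controlled correlations, not quantitative agreement with any particular
flow.

Canonical study conditions (the `turbulent_surrogate` config): N = 500
sensors, radius R = 25, domain x ∈ [λ, 30λ] with a uniform prior on the
same rectangle, a 9×3 test grid spanning x/L ∈ [0.1, 0.95] with rows at
y = 0, ±30 (inside the cone at every test column), 50 realizations per
location, and realizations with fewer than 2 detections excluded. The
latent correlation length is 5 grid units — the odor-filament scale, well
below the agent radius, as in resolved turbulence simulations where
filament widths sit near the grid/Kolmogorov scale — and snapshots
decorrelate over 5 sampling intervals (irrelevant for the instantaneous
studies, which draw one snapshot per realization). An earlier candidate
with correlation length equal to R was rejected at design time: the disc
then spans ~2 patches, every location becomes information-starved, and
near-source off-axis locations register zero detections in every
realization — a degenerate study rather than a harder one.

Sensors read the nearest latent-patch node (binary fields are not
interpolated); the patch spacing ℓ_c/3 resolves the kernel, and sensors
closer than one patch cell share a value, which is below the correlation
scale anyway.

## Noise mechanisms and corrections

Positional blurs (proprioceptive and positional mechanisms) draw each
coordinate from N(0, η²) truncated to ±(η+1); the 2-D blur is applied
independently per coordinate. Flip noise toggles each detection with
probability η; raw noise adds N(0, η²) to the concentration proxy before
thresholding. Error-corrected inference replaces the per-sensor detection
probability with its expectation under the known noise level: the exact
mixture η₀ + (1−2η₀)ℓ for flip; the truncated-Gaussian-convolved map for
the positional mechanisms; and, for raw noise, a two-point signal proxy
(background 0, burst 2c₀) — an acknowledged approximation, since the
likelihood map carries no raw-signal distribution.

The published fixed-noise levels are internally inconsistent between the
running text (flip 0.01, raw 0.001·c₀) and the figure caption
(flip 0.001, raw 0.01); the four-mechanism comparison here uses
(25, 25, 0.001, 0.01). Under the log-normal raw proxy a raw noise of
0.001·c₀ flips essentially no sensors, so the alternative reading is a
no-op by construction; both readings are exposed through the config.

## Asymptotic theory

The infinite-N estimator with perceived positions blurred at scale σ
maximizes F(ξₓ) = E_{ϕ~N((ξₓ,0), σ²I)}[θ ln ℓ(ϕ) + (1−θ) ln(1−ℓ(ϕ))]
along the centerline — the law-of-large-numbers limit of the MAP sum,
with the expectation outside the logarithm because detections and
perceived offsets are independent. The 2-D Gauss–Hermite quadrature
(order 32 per axis) and the candidate grid are precomputed per σ, so each
(θ, σ) estimate is a table argmax; θ = 0 returns the prior's far edge
exactly (the analytic limit, not left to quadrature resolution). The
verified limits: at σ = 0 the estimate inverts the centerline likelihood,
x̂ = λθ^(−1/δ); at large σ estimates collapse across θ onto x̂ ∝ σ with
coefficient near √(2/δ)/β. Between the limits the estimator is
non-monotone in σ — it dips below the truth before the detection-pair
branch takes over, the "elbow" visible in realizations that over-detect —
and this dip is confirmed by direct Monte-Carlo of the finite-N estimator,
not a quadrature artifact.

The finite-N optimum σ*(x, N) bootstraps θ̂ ~ Binomial(N, ℓ(x,0))/N and
reads each draw through the precomputed tables (the same read-out used in
the original analysis). Because the read-out deliberately omits
offset-sampling noise, at very large N its argmin settles on the bias
zero-crossing near ⅔·a* rather than exactly 0; the meaningful large-N
statement — and the one asserted in the tests — is that σ = 0 inference is
already essentially perfect and the absolute advantage of tuning vanishes
(it shrinks by two orders of magnitude between N = 10 and N = 10⁴ at the
tested positions).

## Statistical design of the scans

Noise scans use common random numbers: sensor placement and the odor
snapshot are seeded by (master seed, location, realization) only, while
noise draws add a condition key, so compared conditions differ only
through the noise itself. Exclusions (fewer than 2 detections) depend
only on the snapshot, hence are identical across compared noise levels of
the proprioceptive mechanism. The region split follows the canonical
31-column layout (11/10/10 columns); other layouts fall back to
x-terciles.

"Benefit of tuned noise" is measured cross-validated: η* is selected on
even-numbered realizations and evaluated on odd-numbered ones, because an
argmin over a grid of noisy MSE estimates is biased low and would
manufacture apparent benefit where none exists (this matters for the
near-source region and the isotropic controls; the far-region effect is an
order of magnitude and indifferent to the protocol). Significance is a
bootstrap CI over realizations of the pooled squared-error difference.

## Known limitations

- The candidate grid quantizes estimates to the field lattice (20×12 grid
  units in the canonical configs); all tolerances are stated in grid cells.
- The empirical-noise rule inverts the *anisotropic centerline* likelihood;
  it is not defined for isotropic fields (where no tuning is beneficial
  anyway).
- The raw-noise correction's two-point signal proxy is the weakest link of
  the correction family; it is flagged as such and only its qualitative
  ordering is tested.
- Single-sensor time-series inference assumes a fixed agent; no motion or
  sequential policy (infotaxis-style) is modelled anywhere.
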