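# plumeloc

Bayesian odor-source localization from binary multisensor arrays in
turbulent plumes — and the counterintuitive benefit of positional noise.

## The problem

An agent carrying N chemical sensors scattered in a disc of radius R (think
of an octopus arm's suckers, or a swarm of cheap gas sensors on a robot)
takes one instantaneous set of binary odor detections m_i ∈ {0, 1} and must
infer where it sits relative to an odor source in a turbulent flow. The
agent knows the stationary *likelihood map* ℓ(ϕ) — the probability that
the odor concentration at position ϕ (relative to the source) exceeds its
sensitivity threshold c₀ — and maximizes the posterior

    ξ̂ = argmax_ξ Σᵢ [ mᵢ ln ℓ(ξ + δᵢ) + (1 − mᵢ) ln(1 − ℓ(ξ + δᵢ)) ]

over a uniform prior rectangle, where δᵢ are the *perceived* sensor offsets.
In a mean flow the map is anisotropic and conical,

    ℓ(ϕ) = min(1, (ϕₓ/λ)^(−δ) · exp(−ϕ_y² / (β² ϕₓ²))),

with decay lengthscale λ, decay exponent δ and cone half-angle β (all
lengths in grid-spacing units; canonical values λ = 96.86, δ = 1.54,
β = 0.08).

The surprise this package reproduces: when detections are corrupted by
turbulent spatiotemporal correlations, *blurring the perceived sensor
positions with Gaussian noise of scale η improves the estimates* far from
the source. Noise inflates the perceived size of the agent to σ ≈ R + η,
and two detections perceived at (x, ±a) pin the estimate to
x̂ = a·√(2/δ)/β — so σ acts as a tunable knob, with optimum
σ* ≲ a*(x) = x·β·√(δ/2), and an observation-driven ("empirical") setting
η̂ = max(0, a*(x(θ̂)) − R) computable from the detected fraction θ̂ alone.
On isotropic plumes, where geometry carries no information, the benefit
disappears.

The package provides:

- `plume` — conical/isotropic likelihood models, gridded empirical maps,
  a statsmodels-style fit (`ConicalPlumeModel(...).fit().summary()`),
  centerline inversion and contour geometry;
- `synth` — surrogate odor snapshots: independent Bernoulli draws or a
  thresholded correlated Gaussian field (Gaussian copula) with exact
  marginals and tunable correlation length/time, plus a positive
  raw-concentration proxy;
- `inference` — sensor placement, the four noise mechanisms
  (proprioceptive, positional, flip, raw), the MAP grid-search estimator,
  single-sensor time-series inference, and noise-aware ("error-corrected")
  likelihoods;
- `theory` — detection-pair closed forms, the infinite-N asymptotic
  estimator, finite-N bootstrap of the optimal perceived size, empirical
  noise tuning;
- `experiments` — a config-driven scenario runner with common random
  numbers across compared conditions, MSE/bias metrics, region
  aggregation, baselines, and the `plumeloc` CLI
  (`generate` / `infer` / `scan` / `compare` / `report`).

## Worked example

```python
import numpy as np
from plumeloc import (PlumeParams, LikelihoodField, sample_bernoulli,
                      empirical_likelihood, ConicalPlumeModel,
                      optimal_pair_distance, empirical_noise, PriorBox)

params = PlumeParams()                       # λ=96.86, δ=1.54, β=0.08
lam = params.lambda_scale
grid = LikelihoodField.from_params(
    params, np.linspace(1.2 * lam, 6 * lam, 60), np.linspace(-55, 55, 40))

# fit the plume model to detection frequencies from 200 binary snapshots
emp = empirical_likelihood(sample_bernoulli(grid, 200, seed=1))
fit = ConicalPlumeModel(emp).fit()
print(fit.summary())
```

prints

```
Conical plume likelihood fit
============================================
parameter         estimate     std err
--------------------------------------------
lambda_scale       97.6430      0.7069
delta_exp           1.5482      0.0100
beta_width          0.0799      0.0003
--------------------------------------------
centerline nodes: 60   lateral nodes: 1724
```

— the three generating parameters recovered to better than 1%, with
standard errors from the binomial GLM behind the fit. The theory side is
two closed forms away:

```python
prior = PriorBox(lam, 30 * lam, -150, 150)
a_star = optimal_pair_distance(500.0, params)        # 35.10
eta_hat = empirical_noise(0.0798, params, radius=25.0, prior=prior)  # 10.10
```

A detection pair perceived 2×35.1 apart estimates x = 500 exactly, so an
agent of radius 25 that measures a detected fraction θ̂ = 0.0798 (the
centerline likelihood at x = 500) should blur its proprioception by
η̂ ≈ 10.1 grid units.

Full scenario runs are driven by YAML configs (see `configs/`):

```
plumeloc scan  --config configs/turbulent_desk.yaml --seed 1 --out out/scan
plumeloc infer --config configs/turbulent_desk.yaml --seed 1 --out out/run0
plumeloc report --records out/run0/records.csv
```

On the correlated anisotropic surrogate this reproduces the headline
pattern: tuned noise lowers far-region MSEx severalfold, the optimal η*
grows with distance and tracks a*(x) − R, and the empirical tuning η̂(θ̂)
lands between perfect proprioception and optimal tuning. The same scans on
isotropic fields show no benefit.

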