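"""Multisensor Bayesian MAP localization under positional and sensory noise.

An agent is a cloud of ``N`` binary sensors drawn uniformly in a disc of
radius ``R`` around its center.  From one snapshot of detections ``m_i``
and the *perceived* sensor offsets ``d_i`` it maximizes the log-posterior

    sum_i [ m_i ln l(xi + d_i) + (1 - m_i) ln(1 - l(xi + d_i)) ]

over candidate centers ``xi`` on the field lattice inside a uniform prior
rectangle (the source sits at the origin, so the likelihood of a detection
at absolute position ``phi`` is the plume map ``l(phi)``).

Four noise mechanisms are supported:

- ``proprioceptive``: the perceived offsets are blurred, the detections are
  not — noise affects only the processing, and inflates the perceived size
  of the agent to ``R + eta``;
- ``positional``: the real sampling positions are blurred while the agent
  keeps using the nominal offsets;
- ``flip``: each binary detection is flipped independently with
  probability ``eta``;
- ``raw``: additive Gaussian noise on the raw concentration before
  thresholding at ``c0``.

Positional blurs are zero-mean Gaussians of standard deviation ``eta``
truncated to ``[-(eta+1), eta+1]`` per coordinate.  Error-corrected
variants replace the per-sensor detection probability with its expectation
under the known noise level and then maximize the same surface.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from ._util import as_rng
from .plume import LikelihoodField
from .synth import binarize

__all__ = [
    "AgentGeometry",
    "NoiseSpec",
    "Observation",
    "EstimateRecord",
    "place_sensors",
    "truncated_gaussian_noise",
    "apply_noise",
    "map_estimate",
    "map_argmax",
    "corrected_field",
    "corrected_log_likelihood",
    "single_sensor_timeseries_map",
    "perceived_size",
    "MECHANISMS",
]

MECHANISMS = ("proprioceptive", "positional", "flip", "raw")


@dataclass
class AgentGeometry:
    """Sensor cloud: center, radius, real and perceived sensor offsets."""

    center: np.ndarray
    radius: float
    offsets: np.ndarray
    perceived_offsets: np.ndarray | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.offsets = np.atleast_2d(np.asarray(self.offsets, dtype=float))
        if np.any(np.hypot(self.offsets[:, 0], self.offsets[:, 1]) > self.radius + 1e-9):
            raise ValueError("sensor offsets must lie within the disc of radius R")
        if self.perceived_offsets is None:
            self.perceived_offsets = self.offsets.copy()
        else:
            self.perceived_offsets = np.atleast_2d(
                np.asarray(self.perceived_offsets, dtype=float)
            )

    @property
    def n_sensors(self) -> int:
        return self.offsets.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return self.center + self.offsets


@dataclass(frozen=True)
class NoiseSpec:
    """Noise mechanism and magnitude.

    ``eta`` is a length (grid-spacing units) for proprioceptive/positional
    noise, a flip probability (<= 0.5) for ``flip``, and a raw-signal
    standard deviation for ``raw``.
    """

    mechanism: str
    eta: float

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.mechanism == "flip" and self.eta > 0.5:
            raise ValueError("flip probability must be <= 0.5")


@dataclass
class Observation:
    """Binary detections plus the perceived offsets used by the estimator."""

    detections: np.ndarray
    perceived_offsets: np.ndarray

    def __post_init__(self):
        self.detections = np.asarray(self.detections).astype(np.uint8)
        self.perceived_offsets = np.atleast_2d(
            np.asarray(self.perceived_offsets, dtype=float)
        )
        if self.detections.shape[0] != self.perceived_offsets.shape[0]:
            raise ValueError("detections and perceived offsets disagree in length")

    @property
    def theta_hat(self) -> float:
        return float(self.detections.mean())

    @property
    def n_detections(self) -> int:
        return int(self.detections.sum())


@dataclass
class EstimateRecord:
    """One inference realization."""

    truth: tuple
    estimate: tuple
    mechanism: str
    eta: float
    theta_hat: float
    n_detections: int
    seed: int | None = None
    excluded: bool = False


def place_sensors(center, radius: float, n_sensors: int, seed) -> AgentGeometry:
    """Draw ``n_sensors`` offsets i.i.d. area-uniform in the disc of radius R."""
    if radius <= 0 or n_sensors < 1:
        raise ValueError("need radius > 0 and n_sensors >= 1")
    rng = as_rng(seed)
    r = radius * np.sqrt(rng.random(n_sensors))
    ang = rng.random(n_sensors) * 2.0 * np.pi
    offsets = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return AgentGeometry(np.asarray(center, dtype=float), radius, offsets)


def truncated_gaussian_noise(eta: float, count: int, seed) -> np.ndarray:
    """(count, 2) blur vectors; each coordinate ~ N(0, eta^2) truncated to
    [-(eta+1), eta+1].  ``eta = 0`` returns zeros."""
    if eta < 0:
        raise ValueError("eta must be non-negative")
    if eta == 0:
        return np.zeros((count, 2))
    rng = as_rng(seed)
    bound = (eta + 1.0) / eta
    return stats.truncnorm.rvs(
        -bound, bound, scale=eta, size=(count, 2), random_state=rng
    )


def perceived_size(radius: float, eta: float) -> float:
    """Effective radius of the sensor cloud as seen by the estimator, R + eta."""
    if radius < 0 or eta < 0:
        raise ValueError("radius and eta must be non-negative")
    return radius + eta


def apply_noise(
    geometry: AgentGeometry,
    noise: NoiseSpec,
    sampler,
    seed,
    c0: float | None = None,
) -> Observation:
    """Read one snapshot through ``sampler`` under the given noise mechanism.

    ``sampler`` is any object with ``sample(points, rng, with_raw=...)``
    (e.g. :class:`plumeloc.synth.PlumeSampler`), or a pre-drawn snapshot
    wrapped by :func:`snapshot_reader`.  Two independent streams are derived
    from ``seed``: one for the snapshot itself, one for the noise draws, so
    that the same odor realization can be re-read under different noise
    levels.
    """
    rng_noise = as_rng(seed)
    mech, eta = noise.mechanism, noise.eta
    offsets = geometry.offsets
    n = geometry.n_sensors

    if mech == "positional":
        gamma = truncated_gaussian_noise(eta, n, rng_noise)
        real_pts = geometry.center + offsets + gamma
        det = np.asarray(sampler.sample(real_pts, rng_noise))
        return Observation(det, offsets)

    pts = geometry.center + offsets
    if mech == "raw":
        if c0 is None:
            c0 = getattr(sampler, "c0", None)
        if c0 is None:
            raise ValueError("raw mechanism requires the threshold c0")
        det, raw = sampler.sample(pts, rng_noise, with_raw=True)
        raw = np.asarray(raw, dtype=float) + eta * rng_noise.standard_normal(n)
        return Observation(binarize(raw, c0), offsets)

    det = np.asarray(sampler.sample(pts, rng_noise))
    if mech == "flip":
        flips = rng_noise.random(n) < eta
        det = np.where(flips, 1 - det, det)
        return Observation(det, offsets)

    # proprioceptive: detections untouched, perceived offsets blurred
    gamma = truncated_gaussian_noise(eta, n, rng_noise)
    return Observation(det, offsets + gamma)


# ---------------------------------------------------------------------------
# MAP estimation
# ---------------------------------------------------------------------------


def map_argmax(obs: Observation, field: LikelihoodField, p_floor: float = 1e-6):
    """Argmax of the log-posterior over the field lattice inside the prior.

    Perceived offsets are rounded to whole lattice steps, so every candidate
    evaluation is a table lookup; positions falling off the grid read the
    nearest edge node.  Ties break to the smallest x, then smallest y
    (candidates are scanned in (x, y)-lexicographic order).
    """
    logl, log1ml = field.log_tables(p_floor)
    ci, cj = field.prior_node_indices()
    di = np.rint(obs.perceived_offsets[:, 0] / field.dx).astype(np.intp)
    dj = np.rint(obs.perceived_offsets[:, 1] / field.dy).astype(np.intp)
    nx, ny = field.shape
    det = obs.detections.astype(bool)
    # sensors sharing a lattice offset contribute identically: aggregate
    # into unique (di, dj) cells with detection / non-detection counts
    code = (di - di.min()) * (dj.max() - dj.min() + 1) + (dj - dj.min())
    uniq, inv = np.unique(code, return_inverse=True)
    c1 = np.bincount(inv[det], minlength=uniq.size).astype(float)
    c0 = np.bincount(inv[~det], minlength=uniq.size).astype(float)
    first = np.zeros(uniq.size, dtype=np.intp)
    first[inv[::-1]] = np.arange(len(inv) - 1, -1, -1)
    udi, udj = di[first], dj[first]
    ix = np.clip(ci[:, None] + udi[None, :], 0, nx - 1)
    iy = np.clip(cj[:, None] + udj[None, :], 0, ny - 1)
    flat = ix * ny + iy
    lp = logl.ravel()[flat] @ c1 + log1ml.ravel()[flat] @ c0
    k = int(np.argmax(lp))
    return (float(field.x[ci[k]]), float(field.y[cj[k]])), lp


def map_estimate(
    obs: Observation,
    field: LikelihoodField,
    p_floor: float = 1e-6,
    truth=(np.nan, np.nan),
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    min_detections: int | None = None,
) -> EstimateRecord:
    """MAP source-center estimate from one multisensor observation."""
    (xh, yh), _ = map_argmax(obs, field, p_floor)
    excluded = (
        min_detections is not None and obs.n_detections < min_detections
    )
    return EstimateRecord(
        truth=tuple(float(t) for t in truth),
        estimate=(xh, yh),
        mechanism=noise.mechanism if noise else "none",
        eta=noise.eta if noise else 0.0,
        theta_hat=obs.theta_hat,
        n_detections=obs.n_detections,
        seed=seed,
        excluded=bool(excluded),
    )


def single_sensor_timeseries_map(
    series,
    offset,
    field: LikelihoodField,
    stride: int = 1,
    n_points: int | None = None,
    p_floor: float = 1e-6,
    truth=(np.nan, np.nan),
) -> EstimateRecord:
    """MAP estimate from a strided time series of one sensor's detections.

    The posterior is the product of per-time Bernoulli likelihoods at a
    single sensor offset — formally identical to a multisensor observation
    with all sensors at the same place.
    """
    series = np.asarray(series).ravel()[::stride]
    if n_points is not None:
        series = series[:n_points]
    if series.size < 1:
        raise ValueError("need at least one time point")
    offs = np.tile(np.asarray(offset, dtype=float), (series.size, 1))
    obs = Observation(series, offs)
    return map_estimate(obs, field, p_floor=p_floor, truth=truth)


# ---------------------------------------------------------------------------
# Error-corrected likelihoods
# ---------------------------------------------------------------------------


def corrected_field(
    field: LikelihoodField,
    noise: NoiseSpec,
    c0: float = 1.0,
    burst_factor: float = 2.0,
) -> LikelihoodField:
    """Likelihood map an agent should use when it knows its own noise level.

    - ``flip``: ``l' = eta0 + (1 - 2 eta0) l`` (non-identifiable at
      eta0 >= 0.5).
    - ``proprioceptive`` / ``positional``: the truncated-Gaussian-blurred
      map ``l'(phi) = E_gamma[l(phi + gamma)]`` (separable discrete
      convolution on the lattice).
    - ``raw``: a two-point raw-signal proxy with background level 0 and
      burst level ``burst_factor * c0``:
      ``l' = l * Phi((c1 - c0)/eta0) + (1 - l) * Phi(-c0/eta0)``.
    """
    eta = noise.eta
    vals = field.values
    if noise.mechanism == "flip":
        if eta >= 0.5:
            raise ValueError("flip correction is non-identifiable for eta0 >= 0.5")
        new = eta + (1.0 - 2.0 * eta) * vals
    elif noise.mechanism in ("proprioceptive", "positional"):
        new = _blur_truncnorm(vals, eta, field.dx, field.dy)
    elif noise.mechanism == "raw":
        if eta == 0:
            new = vals.copy()
        else:
            c1 = burst_factor * c0
            p_hit = stats.norm.cdf((c1 - c0) / eta)
            p_false = stats.norm.cdf(-c0 / eta)
            new = vals * p_hit + (1.0 - vals) * p_false
    else:  # pragma: no cover - NoiseSpec already validates
        raise ValueError(noise.mechanism)
    out = LikelihoodField(field.x, field.y, np.clip(new, 0.0, 1.0), field.prior)
    return out


def _blur_truncnorm(values, eta, dx, dy):
    if eta == 0:
        return values.copy()
    out = values
    for axis, h in ((0, dx), (1, dy)):
        radius = int(np.floor((eta + 1.0) / h))
        if radius < 1:
            continue
        offs = h * np.arange(-radius, radius + 1)
        bound = (eta + 1.0) / eta
        w = stats.truncnorm.pdf(offs / eta, -bound, bound) / eta
        w /= w.sum()
        out = ndimage.convolve1d(out, w, axis=axis, mode="nearest")
    return out


def corrected_log_likelihood(
    obs: Observation,
    field: LikelihoodField,
    noise: NoiseSpec,
    p_floor: float = 1e-6,
    c0: float = 1.0,
):
    """Log-posterior surface over the prior lattice using the corrected map.

    Returns ``(candidates, surface, argmax)`` where candidates is an (G, 2)
    array of lattice points.  With ``eta = 0`` the surface is identical to
    the uncorrected one.
    """
    cfield = corrected_field(field, noise, c0=c0)
    (xh, yh), lp = map_argmax(obs, cfield, p_floor)
    ci, cj = cfield.prior_node_indices()
    cands = np.column_stack([cfield.x[ci], cfield.y[cj]])
    return cands, lp, (xh, yh)
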