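"""Surrogate odor snapshots: independent Bernoulli or correlated binary fields.

Real turbulent plumes produce binary detection fields with strong
spatiotemporal correlations: patches of odor sweep past, so nearby sensors
tend to agree.  This module emulates that with a thresholded correlated
Gaussian (a Gaussian copula): a latent zero-mean, unit-variance field
``g(phi, t)`` with a squared-exponential spatial kernel

    corr[g(phi), g(phi + d)] = exp(-|d|^2 / (2 corr_length^2))

and AR(1) temporal correlation is thresholded node-by-node at the standard
normal upper quantile of the target detection probability ``l(phi)``.  The
construction preserves the marginal likelihood map exactly for every
correlation setting, while the correlation length and time are free knobs.
Setting both to zero recovers independent Bernoulli sampling.

A strictly positive raw-concentration proxy ``c = c0 * exp(s (g - z))`` is
derived from the same latent field, so thresholding the raw signal at
``c0`` reproduces the binary snapshot identically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from ._util import as_rng
from .plume import LikelihoodField

__all__ = [
    "CorrelationSpec",
    "SnapshotSet",
    "sample_bernoulli",
    "sample_correlated",
    "raw_from_latent",
    "binarize",
    "latent_threshold",
    "PlumeSampler",
]


@dataclass(frozen=True)
class CorrelationSpec:
    """Spatiotemporal correlation of the latent Gaussian field.

    corr_length : spatial correlation length of the latent field (grid-
        spacing units); 0 means spatially independent nodes.
    corr_time : temporal e-folding scale in snapshot intervals (AR(1)
        coefficient ``exp(-1/corr_time)``); 0 means independent snapshots.
    kernel : spatial covariance family; only "squared-exponential" is
        implemented.
    """

    corr_length: float = 0.0
    corr_time: float = 0.0
    kernel: str = "squared-exponential"

    def __post_init__(self):
        if self.corr_length < 0 or self.corr_time < 0:
            raise ValueError("correlation scales must be non-negative")
        if self.kernel != "squared-exponential":
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def ar1(self) -> float:
        return float(np.exp(-1.0 / self.corr_time)) if self.corr_time > 0 else 0.0


@dataclass
class SnapshotSet:
    """Binary (and optionally raw) odor snapshots on a grid.

    ``binary`` has shape (nt, nx, ny); ``raw``, when present, satisfies
    ``raw >= c0  <=>  binary == 1`` node by node.
    """

    x: np.ndarray
    y: np.ndarray
    binary: np.ndarray
    raw: np.ndarray | None = None
    c0: float | None = None
    seed: int | None = None
    corr: CorrelationSpec | None = None

    def __post_init__(self):
        self.binary = np.asarray(self.binary)
        if not np.isin(self.binary, (0, 1)).all():
            raise ValueError("binary values must be in {0, 1}")
        if self.raw is not None:
            if self.c0 is None:
                raise ValueError("raw snapshots require c0")
            if not np.array_equal(self.raw >= self.c0, self.binary.astype(bool)):
                raise ValueError("raw/binary threshold inconsistency")

    @property
    def n_snapshots(self) -> int:
        return self.binary.shape[0]

    def to_text(self, path) -> None:
        """Write as a flat text container (binary values; header metadata)."""
        nt, nx, ny = self.binary.shape
        dx = float(self.x[1] - self.x[0]) if self.x.size > 1 else 1.0
        dy = float(self.y[1] - self.y[0]) if self.y.size > 1 else 1.0
        corr = self.corr or CorrelationSpec(0.0, 0.0)
        header = (
            f"plumeloc snapshot set\n"
            f"x0 {float(self.x[0])!r} dx {dx!r} nx {nx}\n"
            f"y0 {float(self.y[0])!r} dy {dy!r} ny {ny}\n"
            f"nt {nt} seed {self.seed if self.seed is not None else 'none'}\n"
            f"corr_length {corr.corr_length!r} corr_time {corr.corr_time!r}\n"
            f"values: nt*nx*ny row-major"
        )
        np.savetxt(path, self.binary.reshape(nt, -1), fmt="%d", header=header)

    @classmethod
    def from_text(cls, path) -> "SnapshotSet":
        from pathlib import Path

        meta = {}
        for ln in Path(path).read_text().splitlines():
            if not ln.startswith("#"):
                break
            tok = ln[1:].split()
            if tok and tok[0] in ("x0", "y0"):
                meta[tok[0][0]] = (float(tok[1]), float(tok[3]), int(tok[5]))
            elif tok and tok[0] == "nt":
                meta["nt"] = int(tok[1])
                meta["seed"] = None if tok[3] == "none" else int(tok[3])
            elif tok and tok[0] == "corr_length":
                meta["corr"] = CorrelationSpec(float(tok[1]), float(tok[3]))
        (x0, dx, nx), (y0, dy, ny) = meta["x"], meta["y"]
        vals = np.loadtxt(path, dtype=np.uint8).reshape(meta["nt"], nx, ny)
        return cls(
            x0 + dx * np.arange(nx), y0 + dy * np.arange(ny), vals,
            seed=meta["seed"], corr=meta.get("corr"),
        )


def latent_threshold(prob: np.ndarray) -> np.ndarray:
    """Standard-normal upper quantile z with P(g >= z) = prob."""
    return stats.norm.isf(np.clip(prob, 1e-12, 1.0 - 1e-12))


def binarize(raw, c0: float) -> np.ndarray:
    """Threshold raw concentrations: 1 iff ``raw >= c0`` (inclusive)."""
    return (np.asarray(raw) >= c0).astype(np.uint8)


def raw_from_latent(latent, field_or_prob, c0: float, scale: float = 1.0) -> np.ndarray:
    """Raw-concentration proxy ``c = c0 * exp(scale * (g - z))``.

    ``g = z`` sits exactly on the threshold, so ``binarize(raw, c0)``
    equals the binary snapshot obtained from the same latent field.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    prob = (
        field_or_prob.values if isinstance(field_or_prob, LikelihoodField) else field_or_prob
    )
    z = latent_threshold(np.asarray(prob, dtype=float))
    return c0 * np.exp(scale * (np.asarray(latent, dtype=float) - z))


def sample_bernoulli(field: LikelihoodField, n_snapshots: int, seed, points=None):
    """Independent Bernoulli draws from the likelihood map.

    With ``points=None`` returns a :class:`SnapshotSet` on the field grid;
    with an (n, 2) array of absolute positions returns a (n_snapshots, n)
    binary array drawn at the nearest-node probabilities.
    """
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    rng = as_rng(seed)
    if points is not None:
        p = field.value_at(points)
        return (rng.random((n_snapshots, p.size)) < p).astype(np.uint8)
    p = field.values
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities outside [0, 1]")
    binary = (rng.random((n_snapshots,) + p.shape) < p).astype(np.uint8)
    return SnapshotSet(
        field.x, field.y, binary,
        seed=seed if np.isscalar(seed) else None,
        corr=CorrelationSpec(0.0, 0.0),
    )


def _filter_sigma(corr_length: float, spacing: float) -> float:
    # filtering white noise with a Gaussian of std sigma_f yields a
    # squared-exponential covariance of length sqrt(2) * sigma_f
    return corr_length / (np.sqrt(2.0) * spacing)


def _filter_norm(sigma: float) -> float:
    """l2 norm of the discrete Gaussian filter scipy applies (truncate=4)."""
    if sigma <= 0:
        return 1.0
    radius = int(4.0 * sigma + 0.5)
    imp = np.zeros(2 * radius + 1)
    imp[radius] = 1.0
    w = ndimage.gaussian_filter1d(imp, sigma)
    return float(np.sqrt(np.sum(w**2)))


def _correlated_unit_field(shape, sigmas, rng) -> np.ndarray:
    """Unit-variance Gaussian field with separable squared-exponential kernel.

    Generated on a padded grid and cropped so boundary handling cannot leak
    into the returned region.
    """
    pads = [int(4.0 * s + 0.5) if s > 0 else 0 for s in sigmas]
    big = rng.standard_normal(tuple(n + 2 * p for n, p in zip(shape, pads)))
    if any(s > 0 for s in sigmas):
        big = ndimage.gaussian_filter(big, sigma=sigmas, mode="constant")
        big /= np.prod([_filter_norm(s) for s in sigmas])
    sl = tuple(slice(p, p + n) for n, p in zip(shape, pads))
    return big[sl]


def sample_correlated(
    field: LikelihoodField,
    corr: CorrelationSpec,
    n_snapshots: int,
    seed,
    with_raw: bool = False,
    c0: float = 1.0,
    raw_scale: float = 1.0,
):
    """Correlated binary snapshots with exact marginals ``l(phi)``.

    The latent field is unit-variance Gaussian with squared-exponential
    spatial correlation of length ``corr.corr_length`` and AR(1) temporal
    correlation; each node is thresholded at its own quantile so the
    long-run detection frequency equals the likelihood at that node.
    """
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    if not (np.isfinite(corr.corr_length) and np.isfinite(corr.corr_time)):
        raise ValueError("correlation scales must be finite")
    rng = as_rng(seed)
    sigmas = (
        _filter_sigma(corr.corr_length, field.dx),
        _filter_sigma(corr.corr_length, field.dy),
    )
    shape = field.shape
    rho = corr.ar1
    latent = np.empty((n_snapshots,) + shape)
    g = _correlated_unit_field(shape, sigmas, rng)
    latent[0] = g
    for t in range(1, n_snapshots):
        w = _correlated_unit_field(shape, sigmas, rng)
        g = rho * g + np.sqrt(1.0 - rho**2) * w
        latent[t] = g
    z = latent_threshold(field.values)
    binary = (latent >= z).astype(np.uint8)
    raw = None
    if with_raw:
        raw = c0 * np.exp(raw_scale * (latent - z))
    return SnapshotSet(
        field.x, field.y, binary, raw=raw, c0=c0 if with_raw else None,
        seed=seed if np.isscalar(seed) else None, corr=corr,
    )


class PlumeSampler:
    """Draw one instantaneous odor snapshot at arbitrary sensor positions.

    This is the engine behind the scenario runner: given the absolute
    positions of an agent's sensors it returns their binary detections (and
    optionally the raw-concentration proxy) for one fresh snapshot.

    For ``corr.corr_length == 0`` every sensor gets an independent latent
    draw.  Otherwise a local latent patch (grid spacing ``corr_length / 3``
    by default) covering the sensors is generated and each sensor reads its
    nearest patch node — binary fields are not interpolated, and sensors
    closer than one patch cell simply share a value, which is below the
    correlation scale anyway.
    """

    def __init__(
        self,
        likelihood_fn,
        corr: CorrelationSpec | None = None,
        c0: float = 1.0,
        raw_scale: float = 1.0,
        patch_spacing: float | None = None,
    ):
        self.likelihood_fn = likelihood_fn
        self.corr = corr if corr is not None else CorrelationSpec(0.0, 0.0)
        self.c0 = c0
        self.raw_scale = raw_scale
        if patch_spacing is None and self.corr.corr_length > 0:
            patch_spacing = self.corr.corr_length / 3.0
        self.patch_spacing = patch_spacing

    def _latent_at(self, points, rng) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if self.corr.corr_length <= 0:
            return rng.standard_normal(pts.shape[0])
        h = self.patch_spacing
        sig = _filter_sigma(self.corr.corr_length, h)
        x0, y0 = pts[:, 0].min(), pts[:, 1].min()
        nx = int(np.ceil((pts[:, 0].max() - x0) / h)) + 1
        ny = int(np.ceil((pts[:, 1].max() - y0) / h)) + 1
        patch = _correlated_unit_field((nx, ny), (sig, sig), rng)
        ix = np.clip(np.rint((pts[:, 0] - x0) / h).astype(int), 0, nx - 1)
        iy = np.clip(np.rint((pts[:, 1] - y0) / h).astype(int), 0, ny - 1)
        return patch[ix, iy]

    def sample(self, points, rng, with_raw: bool = False):
        """Binary detections (and raw proxy) at absolute ``points`` (n, 2)."""
        pts = np.asarray(points, dtype=float)
        prob = np.asarray(self.likelihood_fn(pts), dtype=float)
        z = latent_threshold(prob)
        g = self._latent_at(pts, rng)
        binary = (g >= z).astype(np.uint8)
        if with_raw:
            raw = self.c0 * np.exp(self.raw_scale * (g - z))
            return binary, raw
        return binary
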