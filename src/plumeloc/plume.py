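"""Detection-probability ("likelihood") models of turbulent odor plumes.

The central object is the likelihood map ``l(phi)``: the stationary
probability that an odor concentration measured at position ``phi``
relative to the source exceeds the sensitivity threshold ``c0``.  In the
presence of a mean flow the map is anisotropic and well described by a
conical power-law model

    l(phi) = min(1, (phi_x / lambda)^(-delta) * exp(-phi_y^2 / (beta^2 phi_x^2)))

for downwind positions ``phi_x > 0`` (and 0 upwind), with decay
lengthscale ``lambda``, decay exponent ``delta`` and cone half-angle
``beta``.  All lengths are expressed in grid-spacing units (``dx``).

This module provides the parametric model, empirical (time-averaged)
likelihood maps on rectangular grids, a statsmodels-style fit of the
conical model to an empirical map, centerline inversion, and the contour
geometry used by the detection-pair theory.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "PlumeParams",
    "PriorBox",
    "LikelihoodField",
    "ContourFunction",
    "conical_likelihood",
    "isotropic_likelihood",
    "empirical_likelihood",
    "ConicalPlumeModel",
    "ConicalPlumeFit",
    "fit_conical",
    "invert_centerline",
    "contour_at_level",
    "default_domain",
    "make_field",
]

#: canonical fitted parameters of the anisotropic turbulent plume
DEFAULT_LAMBDA = 96.86
DEFAULT_DELTA = 1.54
DEFAULT_BETA = 0.08


@dataclass(frozen=True)
class PlumeParams:
    """Parameters of the conical (or isotropic) detection-probability model.

    Parameters
    ----------
    lambda_scale : float
        Longitudinal decay lengthscale (grid-spacing units); the likelihood
        on the centerline equals 1 at ``phi_x = lambda_scale``.
    delta_exp : float
        Dimensionless power-law decay exponent.
    beta_width : float
        Dimensionless cone half-angle controlling lateral widening.
    c0 : float
        Concentration threshold in raw-signal units.
    isotropic : bool
        If True the likelihood is the radially symmetric power law
        ``min(1, (r / lambda)^(-delta))`` — the negative control in which
        plume geometry carries no directional information.
    """

    lambda_scale: float = DEFAULT_LAMBDA
    delta_exp: float = DEFAULT_DELTA
    beta_width: float = DEFAULT_BETA
    c0: float = 1.0
    isotropic: bool = False

    def __post_init__(self):
        if not (self.lambda_scale > 0 and self.delta_exp > 0 and self.beta_width > 0):
            raise ValueError("lambda_scale, delta_exp and beta_width must be positive")
        if self.c0 < 0:
            raise ValueError("c0 must be non-negative")

    def likelihood(self, phi) -> np.ndarray:
        """Detection probability at position(s) ``phi`` (shape (..., 2))."""
        if self.isotropic:
            return isotropic_likelihood(self, phi)
        return conical_likelihood(self, phi)


def conical_likelihood(params: PlumeParams, phi) -> np.ndarray:
    """Conical plume detection probability at ``phi`` (shape (..., 2)).

    Returns ``min(1, (phi_x/lambda)^(-delta) * exp(-phi_y^2/(beta^2 phi_x^2)))``
    for ``phi_x > 0`` and 0 for ``phi_x <= 0`` (upwind of the source).
    """
    if params.isotropic:
        raise ValueError("params are isotropic; use isotropic_likelihood")
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite position")
    px, py = phi[..., 0], phi[..., 1]
    down = px > 0
    with np.errstate(divide="ignore", over="ignore"):
        x = np.where(down, px, 1.0)
        val = (x / params.lambda_scale) ** (-params.delta_exp) * np.exp(
            -np.square(py) / (params.beta_width**2 * np.square(x))
        )
    out = np.where(down, np.minimum(1.0, val), 0.0)
    return out[()] if out.ndim == 0 else out


def isotropic_likelihood(params: PlumeParams, phi) -> np.ndarray:
    """Radially symmetric power-law detection probability, ``min(1,(r/lambda)^-delta)``."""
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite position")
    r = np.hypot(phi[..., 0], phi[..., 1])
    with np.errstate(divide="ignore", over="ignore"):
        val = np.where(r > 0, (np.maximum(r, 1e-300) / params.lambda_scale) ** (-params.delta_exp), np.inf)
    return np.minimum(1.0, val)


@dataclass(frozen=True)
class PriorBox:
    """Axis-aligned rectangle of uniform prior support for the agent center."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float

    def __post_init__(self):
        if not (self.x_hi > self.x_lo and self.y_hi > self.y_lo):
            raise ValueError("degenerate prior rectangle")

    def contains(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (
            (pts[..., 0] >= self.x_lo)
            & (pts[..., 0] <= self.x_hi)
            & (pts[..., 1] >= self.y_lo)
            & (pts[..., 1] <= self.y_hi)
        )

    @property
    def x_mid(self) -> float:
        return 0.5 * (self.x_lo + self.x_hi)

    @property
    def var_x(self) -> float:
        """Variance of x under the uniform prior."""
        return (self.x_hi - self.x_lo) ** 2 / 12.0


def default_domain(params: PlumeParams, n_lambda: float = 30.0) -> PriorBox:
    """Canonical prior rectangle: x in [lambda, n*lambda], y symmetric.

    The y half-extent is ``6 * beta * x_hi``, several cone widths at the far
    edge of the domain.
    """
    x_hi = n_lambda * params.lambda_scale
    y_half = 6.0 * params.beta_width * x_hi
    return PriorBox(params.lambda_scale, x_hi, -y_half, y_half)


@dataclass
class LikelihoodField:
    """Detection probability on a uniform rectangular grid.

    ``values[i, j]`` is the probability at ``(x[i], y[j])``.  The prior
    rectangle (uniform prior support for MAP inference) must lie inside the
    grid extent.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    prior: PriorBox
    n_obs: int | None = None  # snapshots behind an empirical mean, if known

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.x.size, self.y.size):
            raise ValueError("values shape must be (len(x), len(y))")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("likelihood values must lie in [0, 1]")
        for c in (self.x, self.y):
            if c.size > 1 and not np.allclose(np.diff(c), c[1] - c[0]):
                raise ValueError("grid must be uniformly spaced")
        if not (
            self.prior.x_lo >= self.x[0] - 0.5 * self.dx
            and self.prior.x_hi <= self.x[-1] + 0.5 * self.dx
            and self.prior.y_lo >= self.y[0] - 0.5 * self.dy
            and self.prior.y_hi <= self.y[-1] + 0.5 * self.dy
        ):
            raise ValueError("prior rectangle not contained in grid extent")
        self._cache: dict = {}

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 1.0

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0]) if self.y.size > 1 else 1.0

    @property
    def shape(self) -> tuple:
        return self.values.shape

    # -- lookup -----------------------------------------------------------
    def index_of(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-node indices of absolute positions, clipped to the grid."""
        pts = np.asarray(points, dtype=float)
        ix = np.rint((pts[..., 0] - self.x[0]) / self.dx).astype(int)
        iy = np.rint((pts[..., 1] - self.y[0]) / self.dy).astype(int)
        return (
            np.clip(ix, 0, self.x.size - 1),
            np.clip(iy, 0, self.y.size - 1),
        )

    def value_at(self, points) -> np.ndarray:
        """Nearest-node detection probability at absolute positions."""
        ix, iy = self.index_of(points)
        return self.values[ix, iy]

    def log_tables(self, p_floor: float = 1e-6):
        """Cached ``(log l, log(1-l))`` with values clamped away from {0, 1}."""
        key = ("log", p_floor)
        if key not in self._cache:
            p = np.clip(self.values, p_floor, 1.0 - p_floor)
            self._cache[key] = (np.log(p), np.log1p(-p))
        return self._cache[key]

    def prior_node_indices(self):
        """Grid-node indices inside the prior, in (x, y)-lexicographic order."""
        if "cand" not in self._cache:
            ii = np.where(
                (self.x >= self.prior.x_lo) & (self.x <= self.prior.x_hi)
            )[0]
            jj = np.where(
                (self.y >= self.prior.y_lo) & (self.y <= self.prior.y_hi)
            )[0]
            if ii.size == 0 or jj.size == 0:
                raise ValueError("empty candidate grid inside prior")
            IX, JY = np.meshgrid(ii, jj, indexing="ij")
            self._cache["cand"] = (IX.ravel(), JY.ravel())
        return self._cache["cand"]

    @property
    def centerline_j(self) -> int:
        return int(np.argmin(np.abs(self.y)))

    # -- constructors & I/O ----------------------------------------------
    @classmethod
    def from_params(
        cls,
        params: PlumeParams,
        x: np.ndarray,
        y: np.ndarray,
        prior: PriorBox | None = None,
    ) -> "LikelihoodField":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        X, Y = np.meshgrid(x, y, indexing="ij")
        vals = params.likelihood(np.stack([X, Y], axis=-1))
        if prior is None:
            prior = PriorBox(x[0], x[-1], y[0], y[-1])
        return cls(x, y, vals, prior)

    def to_text(self, path) -> None:
        """Write as a self-describing flat text grid."""
        header = (
            f"plumeloc likelihood field\n"
            f"x0 {float(self.x[0])!r} dx {self.dx!r} nx {self.x.size}\n"
            f"y0 {float(self.y[0])!r} dy {self.dy!r} ny {self.y.size}\n"
            f"prior {float(self.prior.x_lo)!r} {float(self.prior.x_hi)!r} "
            f"{float(self.prior.y_lo)!r} {float(self.prior.y_hi)!r}\n"
            f"values: nx*ny row-major (x outer)"
        )
        np.savetxt(path, self.values.ravel(), header=header)

    @classmethod
    def from_text(cls, path) -> "LikelihoodField":
        lines = Path(path).read_text().splitlines()
        meta = {}
        for ln in lines:
            if not ln.startswith("#"):
                break
            tok = ln[1:].split()
            if tok and tok[0] in ("x0", "y0"):
                ax = tok[0][0]
                meta[ax] = (float(tok[1]), float(tok[3]), int(tok[5]))
            elif tok and tok[0] == "prior":
                meta["prior"] = tuple(float(t) for t in tok[1:5])
        vals = np.loadtxt(path)
        (x0, dx, nx), (y0, dy, ny) = meta["x"], meta["y"]
        return cls(
            x0 + dx * np.arange(nx),
            y0 + dy * np.arange(ny),
            vals.reshape(nx, ny),
            PriorBox(*meta["prior"]),
        )


def make_field(
    params: PlumeParams,
    x_lo: float | None = None,
    x_hi: float | None = None,
    dx: float = 15.0,
    y_half: float | None = None,
    dy: float = 10.0,
    prior: PriorBox | None = None,
) -> LikelihoodField:
    """Build a gridded likelihood field for ``params``.

    Defaults follow the conical-model conventions: the grid (and prior)
    starts at ``x_lo = lambda`` where the centerline likelihood saturates
    at 1, and extends to ``x_hi = 30 lambda``.
    """
    lam = params.lambda_scale
    x_lo = lam if x_lo is None else x_lo
    x_hi = 30.0 * lam if x_hi is None else x_hi
    if y_half is None:
        y_half = 6.0 * params.beta_width * x_hi
    nx = int(round((x_hi - x_lo) / dx)) + 1
    ny = 2 * int(round(y_half / dy)) + 1
    x = x_lo + dx * np.arange(nx)
    y = -dy * (ny // 2) + dy * np.arange(ny)
    return LikelihoodField.from_params(params, x, y, prior=prior)


def empirical_likelihood(
    snapshots, x=None, y=None, prior: PriorBox | None = None
) -> LikelihoodField:
    """Per-node temporal mean of binary snapshots -> detection probability.

    ``snapshots`` is an array (nt, nx, ny) of {0,1} values (or a SnapshotSet,
    from which grid coordinates are taken unless overridden).
    """
    if hasattr(snapshots, "binary"):
        x = snapshots.x if x is None else x
        y = snapshots.y if y is None else y
        snapshots = snapshots.binary
    arr = np.asarray(snapshots, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("need >= 1 snapshot on a common (nx, ny) grid")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("snapshots must be binary")
    mean = arr.mean(axis=0)
    if x is None:
        x = np.arange(mean.shape[0], dtype=float)
    if y is None:
        y = np.arange(mean.shape[1], dtype=float) - (mean.shape[1] - 1) / 2.0
    if prior is None:
        prior = PriorBox(np.min(x), np.max(x), np.min(y), np.max(y))
    return LikelihoodField(np.asarray(x), np.asarray(y), mean, prior, n_obs=arr.shape[0])


# ---------------------------------------------------------------------------
# Fitting the conical model to an empirical field
# ---------------------------------------------------------------------------


class ConicalPlumeModel:
    """Fit the conical plume model to an empirical likelihood field.

    Away from saturation the conical model is log-linear,

        ln l = delta ln lambda - delta ln phi_x - (phi_y / phi_x)^2 / beta^2,

    so the linear predictor ``[1, ln phi_x, (phi_y/phi_x)^2]`` identifies
    all three parameters: the longitudinal terms from the decay along x,
    the lateral curvature from the Gaussian cross-stream profile.  The
    coefficients are estimated by a binomial GLM with log link on the raw
    detection frequencies (all non-saturated nodes enter, including empty
    ones — selecting only nodes with observed counts in a band would bias
    the far-field decay upward), started from, and falling back to, a
    weighted log-linear regression on nodes inside ``fit_range`` with
    delta-method weights ``w = l / (1 - l)``.
    """

    def __init__(self, field: LikelihoodField, fit_range=(0.01, 0.99)):
        self.field = field
        self.fit_range = fit_range

    def fit(self) -> "ConicalPlumeFit":
        f = self.field
        lo, hi = self.fit_range
        j0 = f.centerline_j
        cl = f.values[:, j0]
        n_center = int(((cl > lo) & (cl < hi) & (f.x > 0)).sum())
        if n_center < 3:
            raise ValueError("fewer than 3 usable centerline nodes")
        X, Y = np.meshgrid(f.x, f.y, indexing="ij")
        band = (f.values > lo) & (f.values < hi) & (X > 0)
        n_lateral = int((band & (np.abs(Y) > 0)).sum())
        if n_lateral < 3:
            raise ValueError("fewer than 3 usable off-centerline nodes")
        # starting values: weighted log-linear regression on the band
        vals = f.values[band]
        A0 = np.column_stack(
            [np.ones(vals.size), np.log(X[band]), np.square(Y[band] / X[band])]
        )
        coef, cov = _wls(A0, np.log(vals), vals / (1.0 - vals))
        if -coef[1] <= 0.05:
            raise ValueError("degenerate fit: no centerline decay")
        if coef[2] >= 0:
            raise ValueError("degenerate fit: no lateral decay")
        # refine on all non-saturated nodes with a log-link binomial GLM
        use = (X > 0) & (f.values < 0.995)
        A = np.column_stack(
            [np.ones(int(use.sum())), np.log(X[use]), np.square(Y[use] / X[use])]
        )
        glm = _glm_log_binomial(f.values[use], A, coef, n_obs=f.n_obs)
        if glm is not None:
            coef, cov = glm
        c0, c1, c2 = coef
        delta = -c1
        if delta <= 0.05:
            raise ValueError("degenerate fit: no centerline decay")
        if c2 >= 0:
            raise ValueError("degenerate fit: no lateral decay")
        lam = float(np.exp(c0 / delta))
        beta = float(np.sqrt(-1.0 / c2))
        # delta-method standard errors from the coefficient covariance
        se_delta = float(np.sqrt(cov[1, 1]))
        g_lam = np.array([lam / delta, lam * c0 / delta**2, 0.0])
        se_lam = float(np.sqrt(g_lam @ cov @ g_lam))
        g_beta = np.array([0.0, 0.0, -0.5 * beta / c2])
        se_beta = float(np.sqrt(g_beta @ cov @ g_beta))

        params = replace(
            PlumeParams(),
            lambda_scale=lam,
            delta_exp=float(delta),
            beta_width=beta,
        )
        return ConicalPlumeFit(
            params=params,
            bse={"lambda_scale": se_lam, "delta_exp": se_delta, "beta_width": se_beta},
            n_centerline=n_center,
            n_lateral=n_lateral,
            model=self,
        )


def _wls(A, y, w):
    """Weighted least squares of y on design A; returns coefs and covariance."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    fitted = A @ coef
    dof = max(len(y) - A.shape[1], 1)
    s2 = float(np.sum(w * (y - fitted) ** 2) / dof)
    cov = s2 * np.linalg.inv((A * w[:, None]).T @ A)
    return coef, cov


def _glm_log_binomial(props, A, start, n_obs=None):
    """Binomial GLM with log link on detection frequencies.

    Returns (coef, cov) or None if the solver fails (caller falls back to
    the weighted log-linear start).
    """
    import warnings

    try:
        import statsmodels.api as sm
    except ImportError:  # pragma: no cover
        return None
    vw = np.full(props.size, float(n_obs)) if n_obs else None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(
                props,
                A,
                family=sm.families.Binomial(link=sm.families.links.Log()),
                var_weights=vw,
            )
            res = model.fit(start_params=start, maxiter=200)
        coef = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not (np.all(np.isfinite(coef)) and np.all(np.isfinite(cov))):
            return None
        return coef, cov
    except Exception:
        return None


@dataclass
class ConicalPlumeFit:
    """Result of :class:`ConicalPlumeModel.fit`."""

    params: PlumeParams
    bse: dict
    n_centerline: int
    n_lateral: int
    model: ConicalPlumeModel

    def summary(self) -> str:
        p = self.params
        rows = [
            ("lambda_scale", p.lambda_scale),
            ("delta_exp", p.delta_exp),
            ("beta_width", p.beta_width),
        ]
        out = [
            "Conical plume likelihood fit",
            "=" * 44,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
            "-" * 44,
        ]
        for name, val in rows:
            out.append(f"{name:<14}{val:>12.4f}{self.bse[name]:>12.4f}")
        out.append("-" * 44)
        out.append(
            f"centerline nodes: {self.n_centerline}   lateral nodes: {self.n_lateral}"
        )
        return "\n".join(out)

    def plot(self, ax=None):
        """Centerline detection frequency (data) against the fitted decay."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.model.field
        j0 = f.centerline_j
        ax.plot(f.x, f.values[:, j0], "o", ms=3, alpha=0.6, label="data")
        fitted = self.params.likelihood(
            np.column_stack([f.x, np.full(f.x.size, f.y[j0])])
        )
        ax.plot(f.x, fitted, "-", label="fit")
        ax.set_xlabel("downwind distance (grid units)")
        ax.set_ylabel("detection probability")
        ax.set_yscale("log")
        ax.legend()
        return ax


def fit_conical(field: LikelihoodField, fit_range=(0.01, 0.99)) -> PlumeParams:
    """Convenience wrapper: fitted :class:`PlumeParams` for ``field``."""
    return ConicalPlumeModel(field, fit_range=fit_range).fit().params


# ---------------------------------------------------------------------------
# Centerline inversion and contour geometry
# ---------------------------------------------------------------------------


def invert_centerline(params: PlumeParams, theta: float, prior: PriorBox) -> float:
    """Downwind distance whose centerline likelihood equals ``theta``.

    Returns ``lambda * theta^(-1/delta)`` clamped to the prior's x-range;
    ``theta = 0`` maps to the far edge and ``theta >= 1`` to ``lambda`` (or
    the prior's near edge if that is larger).
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    if theta <= 0.0:
        return float(prior.x_hi)
    x = params.lambda_scale * theta ** (-1.0 / params.delta_exp)
    return float(np.clip(x, max(prior.x_lo, params.lambda_scale), prior.x_hi))


@dataclass
class ContourFunction:
    """The level set ``l(phi_x, phi_y) = level`` as a half-width profile.

    ``halfwidth(phi_x)`` is the non-negative ``phi_y`` on the contour (NaN
    where the contour does not reach that column); the profile attains its
    maximum ``peak_halfwidth`` at ``peak_x``.
    """

    level: float
    halfwidth: Callable[[np.ndarray], np.ndarray]
    peak_x: float
    peak_halfwidth: float
    x_max: float


def contour_at_level(obj, level: float) -> ContourFunction:
    """Contour of the likelihood at ``level`` for params or a gridded field."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if isinstance(obj, PlumeParams):
        return _contour_parametric(obj, level)
    return _contour_field(obj, level)


def _contour_parametric(params: PlumeParams, level: float) -> ContourFunction:
    if params.isotropic:
        raise ValueError("contour geometry is defined for the anisotropic model")
    lam, delta, beta = params.lambda_scale, params.delta_exp, params.beta_width
    x_max = lam * level ** (-1.0 / delta)

    def halfwidth(phi_x):
        phi_x = np.asarray(phi_x, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = -delta * np.log(phi_x / lam) - np.log(level)
            out = beta * phi_x * np.sqrt(np.where(s >= 0, s, np.nan))
        return np.where(phi_x > 0, out, np.nan)

    peak_x = x_max * np.exp(-0.5)
    peak_hw = beta * peak_x * np.sqrt(delta / 2.0)
    return ContourFunction(level, halfwidth, float(peak_x), float(peak_hw), float(x_max))


def _contour_field(field: LikelihoodField, level: float) -> ContourFunction:
    vals = field.values
    if level > vals.max():
        raise ValueError("level above the field maximum")
    j0 = field.centerline_j
    yy = field.y[j0:]
    half = np.full(field.x.size, np.nan)
    for i in range(field.x.size):
        prof = vals[i, j0:]
        if prof[0] < level:
            continue
        below = np.where(prof < level)[0]
        if below.size == 0:
            half[i] = yy[-1]
            continue
        k = below[0]
        # linear interpolation between the last node above and first below
        y1, y2 = yy[k - 1], yy[k]
        v1, v2 = prof[k - 1], prof[k]
        half[i] = y1 + (level - v1) / (v2 - v1) * (y2 - y1) if v2 != v1 else y1

    def halfwidth(phi_x):
        return np.interp(np.asarray(phi_x, dtype=float), field.x, half)

    i_pk = int(np.nanargmax(half))
    valid = ~np.isnan(half)
    x_max = float(field.x[valid][-1]) if valid.any() else float(field.x[-1])
    return ContourFunction(
        level, halfwidth, float(field.x[i_pk]), float(half[i_pk]), x_max
    )
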