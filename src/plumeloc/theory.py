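"""Geometric and asymptotic theory of noise-enhanced source localization.

Why can blurring sensor positions *help*?  Two detections perceived at
``(x, +-a)`` pin the MAP estimate to the downwind position where the
likelihood contour of half-width ``a`` is widest:

    x_hat(a) = argmax_x  c_a(x),

which for the conical plume model has the closed form
``x_hat = a sqrt(2/delta) / beta``.  The perceived half-distance ``a`` is
therefore a knob on the estimate, and an optimal distance
``a*(x) = x beta sqrt(delta/2)`` recovers the truth exactly.

A cloud of infinitely many sensors whose perceived positions are Gaussian
with scale sigma behaves the same way: its expected log-likelihood

    F(xi_x) = E_{phi ~ N((xi_x, 0), sigma^2 I)}[ theta ln l(phi)
                                               + (1 - theta) ln(1 - l(phi)) ]

is maximized at ``x_hat = lambda theta^(-1/delta)`` when sigma -> 0 (the
detection fraction theta dictates the estimate) and at
``x_hat ~ sigma sqrt(2/delta)/beta`` when sigma is large (the perceived
size dictates it, independent of theta).  For finite N the empirical
detection fraction is noisy, a finite perceived size sigma* > 0 becomes
optimal, and it is bounded by the detection-pair optimum, sigma* <~ a*.
Since proprioceptive noise inflates the perceived size to R + eta, this
yields the empirically computable noise level
``eta_hat = max(0, a*(x_guess) - R)`` with ``x_guess`` inverted from the
observed detection fraction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import as_rng
from .plume import (
    LikelihoodField,
    PlumeParams,
    PriorBox,
    invert_centerline,
)

__all__ = [
    "PairEstimate",
    "pair_estimate",
    "optimal_pair_distance",
    "AsymptoticEstimator",
    "asymptotic_map",
    "SigmaScan",
    "finite_n_optimal_sigma",
    "empirical_noise",
]


@dataclass(frozen=True)
class PairEstimate:
    """Source-distance estimate from two detections at perceived (x, +-a)."""

    a: float
    x_hat: float
    level: float
    method: str


def pair_estimate(a: float, obj, prior: PriorBox | None = None, dx: float | None = None) -> PairEstimate:
    """MAP downwind distance from a detection pair of half-separation ``a``.

    For :class:`PlumeParams` uses the closed form
    ``x_hat = a sqrt(2/delta) / beta``; for a gridded field finds the
    contour level whose peak half-width equals ``a`` numerically.
    """
    if a <= 0:
        raise ValueError("pair half-distance a must be positive")
    if isinstance(obj, PlumeParams):
        if obj.isotropic:
            raise ValueError("pair geometry requires the anisotropic model")
        x_hat = a * np.sqrt(2.0 / obj.delta_exp) / obj.beta_width
        if prior is not None and x_hat > prior.x_hi:
            raise ValueError("a exceeds the maximal contour half-width in the prior")
        # level whose contour peaks at x_hat: peak_x = lam L^(-1/d) e^(-1/2)
        level = (x_hat * np.exp(0.5) / obj.lambda_scale) ** (-obj.delta_exp)
        return PairEstimate(float(a), float(x_hat), float(level), "closed-form")
    return _pair_estimate_field(a, obj)


def _pair_estimate_field(a: float, field: LikelihoodField) -> PairEstimate:
    # argmax over x of l(x, a) * l(x, -a); the probability surface is
    # interpolated linearly in y (it is a smooth field, unlike the binary data)
    def column_at(yv):
        j = np.clip(np.searchsorted(field.y, yv) - 1, 0, field.y.size - 2)
        w = (yv - field.y[j]) / field.dy
        return (1 - w) * field.values[:, j] + w * field.values[:, j + 1]

    prod = column_at(float(np.clip(a, field.y[0], field.y[-1]))) * column_at(
        float(np.clip(-a, field.y[0], field.y[-1]))
    )
    if prod.max() <= 0:
        raise ValueError("a exceeds every contour half-width of the field")
    k = int(np.argmax(prod))
    return PairEstimate(float(a), float(field.x[k]), float(np.sqrt(prod[k])), "numeric")


def optimal_pair_distance(x: float, obj, prior: PriorBox | None = None) -> float:
    """Half-separation ``a*`` whose detection-pair estimate equals ``x``.

    Closed form ``a* = x beta sqrt(delta / 2)`` for the parametric model;
    for a gridded field, solved by root-finding ``pair_estimate(a) = x``.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    if prior is not None and not (prior.x_lo <= x <= prior.x_hi):
        raise ValueError("x outside the prior's x-range")
    if isinstance(obj, PlumeParams):
        if obj.isotropic:
            raise ValueError("pair geometry requires the anisotropic model")
        return float(x * obj.beta_width * np.sqrt(obj.delta_exp / 2.0))
    field = obj
    # dense scan over candidate half-distances; pick the a whose pair
    # estimate lands closest to x (the map a -> x_hat is monotone)
    a_grid = np.arange(field.dy / 4.0, float(field.y[-1]), field.dy / 4.0)
    best_a, best_err = None, np.inf
    for a in a_grid:
        try:
            xh = _pair_estimate_field(float(a), field).x_hat
        except ValueError:
            break
        err = abs(xh - x)
        if err < best_err:
            best_a, best_err = float(a), err
    if best_a is None or best_err > max(2.0 * field.dx, 0.05 * x):
        raise ValueError("x outside representable range of the field")
    return best_a


class AsymptoticEstimator:
    """Infinite-N centerline estimator with Gaussian-blurred positions.

    Precomputes, per perceived size sigma, the tables
    ``A(xi) = E[ln l]`` and ``B(xi) = E[ln(1 - l)]`` over a candidate grid
    along the centerline (2-D Gauss-Hermite quadrature), so that the
    estimate for any detection fraction theta is the argmax of
    ``theta A + (1 - theta) B`` — a vectorized table operation.
    """

    def __init__(
        self,
        params: PlumeParams,
        prior: PriorBox,
        n_grid: int = 400,
        p_floor: float = 1e-6,
        gh_order: int = 32,
    ):
        self.params = params
        self.prior = prior
        self.xs = np.linspace(prior.x_lo, prior.x_hi, n_grid)
        self.p_floor = p_floor
        self._t, self._w = np.polynomial.hermite.hermgauss(gh_order)
        self._tables: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def grid_step(self) -> float:
        return float(self.xs[1] - self.xs[0])

    def tables(self, sigma: float):
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        key = float(sigma)
        if key not in self._tables:
            if sigma == 0:
                phi = np.column_stack([self.xs, np.zeros_like(self.xs)])
                p = np.clip(self.params.likelihood(phi), self.p_floor, 1 - self.p_floor)
                A, B = np.log(p), np.log1p(-p)
            else:
                t, w = self._t, self._w
                # phi = (xi + sqrt(2) s t_j, sqrt(2) s t_k)
                px = self.xs[:, None, None] + np.sqrt(2.0) * sigma * t[None, :, None]
                py = np.sqrt(2.0) * sigma * t[None, None, :]
                phi = np.stack(np.broadcast_arrays(px, py), axis=-1)
                p = np.clip(self.params.likelihood(phi), self.p_floor, 1 - self.p_floor)
                W = (w[:, None] * w[None, :]) / np.pi
                A = np.tensordot(np.log(p), W, axes=([1, 2], [0, 1]))
                B = np.tensordot(np.log1p(-p), W, axes=([1, 2], [0, 1]))
            self._tables[key] = (A, B)
        return self._tables[key]

    def estimate(self, theta, sigma: float) -> np.ndarray:
        """Centerline MAP estimate(s) for detection fraction(s) ``theta``."""
        theta = np.asarray(theta, dtype=float)
        if np.any((theta < 0) | (theta > 1)):
            raise ValueError("theta must lie in [0, 1]")
        A, B = self.tables(sigma)
        F = theta[..., None] * A + (1.0 - theta[..., None]) * B
        k = np.argmax(F, axis=-1)
        out = self.xs[k]
        # theta = 0: no detections, the posterior collapses to the farthest
        # point of the prior (exact limit, independent of quadrature detail)
        out = np.where(theta == 0.0, self.prior.x_hi, out)
        return out if theta.ndim else float(out)


def asymptotic_map(
    theta: float,
    sigma: float,
    params: PlumeParams,
    prior: PriorBox,
    n_grid: int = 400,
    estimator: AsymptoticEstimator | None = None,
) -> float:
    """Infinite-N centerline estimate for detection fraction ``theta`` and
    perceived size ``sigma`` (see :class:`AsymptoticEstimator`)."""
    if estimator is None:
        estimator = AsymptoticEstimator(params, prior, n_grid=n_grid)
    return float(estimator.estimate(float(theta), sigma))


@dataclass
class SigmaScan:
    """MSE of the asymptotic estimator versus perceived size sigma."""

    x: float
    sigmas: np.ndarray
    mse: np.ndarray
    sigma_star: float


def finite_n_optimal_sigma(
    x: float,
    n_sensors: int,
    params: PlumeParams,
    prior: PriorBox,
    sigmas=None,
    n_boot: int = 300,
    seed=0,
    estimator: AsymptoticEstimator | None = None,
) -> SigmaScan:
    """Optimal perceived size for ``n_sensors`` Bernoulli sensors at ``x``.

    Bootstraps the detection fraction ``theta_hat ~ Binom(N, l(x,0)) / N``,
    maps each draw through the asymptotic estimator on a sigma grid, and
    returns the sigma minimizing the mean squared error to ``x`` (ties
    break to the smallest sigma).
    """
    if n_sensors < 1:
        raise ValueError("n_sensors must be >= 1")
    if estimator is None:
        estimator = AsymptoticEstimator(params, prior)
    if sigmas is None:
        a_star = optimal_pair_distance(min(x * 2.0, prior.x_hi), params)
        sigmas = np.linspace(0.0, a_star, 16)
    sigmas = np.asarray(sigmas, dtype=float)
    rng = as_rng(seed)
    p = float(params.likelihood(np.array([x, 0.0])))
    theta = rng.binomial(n_sensors, p, size=n_boot) / n_sensors
    mse = np.empty(sigmas.size)
    for i, s in enumerate(sigmas):
        xh = estimator.estimate(theta, s)
        mse[i] = np.mean((xh - x) ** 2)
    k = int(np.argmin(mse))
    return SigmaScan(float(x), sigmas, mse, float(sigmas[k]))


def empirical_noise(
    theta_hat: float,
    params: PlumeParams,
    radius: float,
    prior: PriorBox,
) -> float:
    """Noise level computable from the observed detection fraction alone.

    Guesses the distance by inverting the centerline likelihood at
    ``theta_hat``, takes the optimal pair distance there, and subtracts the
    real radius: ``eta_hat = max(0, a*(x_guess) - R)``.
    """
    x_guess = invert_centerline(params, theta_hat, prior)
    a_star = optimal_pair_distance(x_guess, params)
    return float(max(0.0, a_star - radius))
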