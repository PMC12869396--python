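"""Config-driven scenario runner, noise scans, metrics and baselines.

A scenario fixes the plume model, the surrogate correlation structure, the
agent (N sensors, radius R), a noise mechanism and level, and a rectangular
grid of test locations; it then runs ``n_realizations`` independent
inference realizations per location and reports per-location mean squared
error and bias.

Seeding uses an addressable counter scheme: the streams for sensor
placement and for the odor snapshot are keyed by (master seed, location,
realization) only, while noise draws are additionally keyed by a condition
index.  Conditions compared against each other (different noise levels or
mechanisms) therefore share sensor clouds and odor realizations — common
random numbers — and differ only in the noise itself.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as _field

import numpy as np
import pandas as pd
import yaml

from ._util import child_rngs
from .inference import (
    MECHANISMS,
    EstimateRecord,
    NoiseSpec,
    Observation,
    corrected_field,
    map_estimate,
    place_sensors,
    truncated_gaussian_noise,
)
from .plume import LikelihoodField, PlumeParams, PriorBox, make_field
from .synth import CorrelationSpec, PlumeSampler, binarize
from .theory import empirical_noise

__all__ = [
    "ScenarioConfig",
    "MetricTable",
    "TuningCurve",
    "run_scenario",
    "optimal_noise_scan",
    "mse_bias",
    "region_aggregate",
    "random_baseline",
    "compare_conditions",
    "records_to_frame",
]

RECORD_COLUMNS = [
    "loc_x", "loc_y", "realization", "x_hat", "y_hat", "mechanism",
    "eta", "theta_hat", "n_detections", "excluded",
]

_EMPIRICAL_KEY = 9999  # condition key for the empirical-noise stream


@dataclass
class ScenarioConfig:
    """Everything needed to reproduce one experiment frame.

    Desk-scale defaults (9x3 test grid, 30 realizations, domain to
    15 lambda) keep a full scenario in the seconds-to-minutes range;
    the geometry is rescalable for full-size runs.
    """

    params: PlumeParams = _field(default_factory=PlumeParams)
    corr_length: float = 0.0
    corr_time: float = 0.0
    n_sensors: int = 500
    radius: float = 25.0
    mechanism: str = "proprioceptive"
    eta: float | str = 0.0  # a number, or "empirical"
    corrected: bool = False
    n_realizations: int = 50
    master_seed: int = 0
    min_detections: int | None = 2
    domain_lambdas: float = 30.0
    field_dx: float = 20.0
    field_dy: float = 12.0
    y_half: float = 144.0
    test_nx: int = 9
    test_ny: int = 3
    test_x_frac: tuple = (0.1, 0.95)
    test_y_half: float = 30.0
    p_floor: float = 1e-6
    raw_scale: float = 1.0
    patch_spacing: float | None = None

    def __post_init__(self):
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if isinstance(self.eta, str) and self.eta != "empirical":
            raise ValueError("eta must be a number or 'empirical'")
        if self.eta == "empirical" and self.mechanism != "proprioceptive":
            raise ValueError("empirical noise tuning is defined for proprioceptive noise")

    @classmethod
    def turbulent_surrogate(cls, **kw) -> "ScenarioConfig":
        """Canonical anisotropic correlated-surrogate study (N=500, R=25).

        The latent correlation length is the odor-filament scale (5 grid
        units, well below the agent radius); snapshots decorrelate over 5
        sampling intervals.
        """
        kw.setdefault("corr_length", 5.0)
        kw.setdefault("corr_time", 5.0)
        return cls(**kw)

    @classmethod
    def isotropic(cls, **kw) -> "ScenarioConfig":
        """Isotropic negative control: radial power-law likelihood."""
        params = kw.pop("params", None) or PlumeParams(isotropic=True)
        if not params.isotropic:
            raise ValueError("isotropic scenario requires isotropic params")
        return cls(params=params, **kw)

    # -- derived objects --------------------------------------------------
    def build_field(self) -> LikelihoodField:
        lam = self.params.lambda_scale
        return make_field(
            self.params,
            x_lo=lam,
            x_hi=self.domain_lambdas * lam,
            dx=self.field_dx,
            y_half=self.y_half,
            dy=self.field_dy,
        )

    def build_sampler(self) -> PlumeSampler:
        corr = CorrelationSpec(self.corr_length, self.corr_time)
        return PlumeSampler(
            self.params.likelihood,
            corr=corr,
            c0=self.params.c0,
            raw_scale=self.raw_scale,
            patch_spacing=self.patch_spacing,
        )

    def test_locations(self, field: LikelihoodField) -> np.ndarray:
        """Test-location grid (nx * ny, 2), snapped to the field lattice."""
        p = field.prior
        f0, f1 = self.test_x_frac
        xs = p.x_lo + np.linspace(f0, f1, self.test_nx) * (p.x_hi - p.x_lo)
        ys = (
            np.linspace(-self.test_y_half, self.test_y_half, self.test_ny)
            if self.test_ny > 1
            else np.array([0.0])
        )
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel()])
        ix, iy = field.index_of(pts)
        return np.column_stack([field.x[ix], field.y[iy]])

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        d["test_x_frac"] = list(self.test_x_frac)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["params"] = PlumeParams(**d.get("params", {}))
        if "test_x_frac" in d:
            d["test_x_frac"] = tuple(d["test_x_frac"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Core realization loop
# ---------------------------------------------------------------------------


def _one_realization(
    config: ScenarioConfig,
    field: LikelihoodField,
    sampler: PlumeSampler,
    center,
    loc_idx: int,
    rep: int,
    mechanism: str,
    eta,
    cond_key: int,
    inference_field: LikelihoodField | None = None,
    prior: PriorBox | None = None,
) -> EstimateRecord:
    rng_place, rng_snap = child_rngs(config.master_seed, loc_idx, rep, n=2)
    (rng_noise,) = child_rngs(config.master_seed, loc_idx, rep, cond_key, n=1)
    geom = place_sensors(center, config.radius, config.n_sensors, rng_place)
    use_field = inference_field if inference_field is not None else field
    empirical = eta == "empirical"

    if mechanism == "positional" and not empirical:
        gamma = truncated_gaussian_noise(eta, geom.n_sensors, rng_noise)
        det = sampler.sample(geom.center + geom.offsets + gamma, rng_snap)
        obs = Observation(det, geom.offsets)
        eta_used = eta
    elif mechanism == "raw" and not empirical:
        det, raw = sampler.sample(geom.positions, rng_snap, with_raw=True)
        raw = raw + eta * rng_noise.standard_normal(geom.n_sensors)
        obs = Observation(binarize(raw, config.params.c0), geom.offsets)
        eta_used = eta
    elif mechanism == "flip" and not empirical:
        det = sampler.sample(geom.positions, rng_snap)
        flips = rng_noise.random(geom.n_sensors) < eta
        obs = Observation(np.where(flips, 1 - det, det), geom.offsets)
        eta_used = eta
    else:  # proprioceptive (fixed or empirical eta)
        det = sampler.sample(geom.positions, rng_snap)
        if empirical:
            theta_hat = float(np.mean(det))
            eta_used = empirical_noise(
                theta_hat, config.params, config.radius, prior or field.prior
            )
        else:
            eta_used = eta
        gamma = truncated_gaussian_noise(eta_used, geom.n_sensors, rng_noise)
        obs = Observation(det, geom.offsets + gamma)

    spec = NoiseSpec(mechanism, float(eta_used))
    return map_estimate(
        obs,
        use_field,
        p_floor=config.p_floor,
        truth=center,
        noise=spec,
        min_detections=config.min_detections,
    )


def records_to_frame(records: list[EstimateRecord], realization=None) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "loc_x": r.truth[0],
                "loc_y": r.truth[1],
                "realization": realization[i] if realization is not None else i,
                "x_hat": r.estimate[0],
                "y_hat": r.estimate[1],
                "mechanism": r.mechanism,
                "eta": r.eta,
                "theta_hat": r.theta_hat,
                "n_detections": r.n_detections,
                "excluded": r.excluded,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def run_scenario(config: ScenarioConfig):
    """Run one scenario; returns ``(records, metrics)``.

    ``records`` is a tidy DataFrame with one row per (location,
    realization); ``metrics`` a :class:`MetricTable` of per-location MSE
    and bias (excluded realizations dropped, counts reported).
    """
    field = config.build_field()
    sampler = config.build_sampler()
    locations = config.test_locations(field)
    mech_idx = MECHANISMS.index(config.mechanism)
    cond_key = _EMPIRICAL_KEY if config.eta == "empirical" else mech_idx
    inference_fld = None
    if config.corrected:
        if config.eta == "empirical":
            raise ValueError("corrected inference requires a fixed eta0")
        inference_fld = corrected_field(
            field, NoiseSpec(config.mechanism, float(config.eta)), c0=config.params.c0
        )
    recs, reps = [], []
    for loc_idx, center in enumerate(locations):
        for rep in range(config.n_realizations):
            recs.append(
                _one_realization(
                    config, field, sampler, center, loc_idx, rep,
                    config.mechanism, config.eta, cond_key,
                    inference_field=inference_fld,
                )
            )
            reps.append(rep)
    records = records_to_frame(recs, realization=reps)
    return records, mse_bias(records)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricTable:
    """Per-location MSE / bias table with exclusion accounting."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        ok = ~t["missing"]
        # variance decomposition sanity: MSE >= bias^2 up to float error
        if not (
            np.all(t.loc[ok, "mse_x"] >= t.loc[ok, "bias_x"] ** 2 - 1e-9)
            and np.all(t.loc[ok, "mse_y"] >= t.loc[ok, "bias_y"] ** 2 - 1e-9)
        ):  # pragma: no cover - arithmetic identity
            raise AssertionError("MSE < bias^2: metric computation is broken")

    @property
    def n_excluded(self) -> int:
        return int(self.table["n_excluded"].sum())

    def aggregate_mse_x(self) -> float:
        ok = ~self.table["missing"]
        return float(self.table.loc[ok, "mse_x"].mean())

    def normalized(self, prior: PriorBox) -> pd.DataFrame:
        """MSE columns divided by the prior variance of x (for reporting)."""
        out = self.table.copy()
        out["mse_x_norm"] = out["mse_x"] / prior.var_x
        return out


def mse_bias(records: pd.DataFrame) -> MetricTable:
    """Per-location MSE and bias of the x and y estimates.

    Excluded realizations are dropped; a location with no usable
    realizations is flagged ``missing``.
    """
    rows = []
    for (lx, ly), grp in records.groupby(["loc_x", "loc_y"], sort=True):
        used = grp[~grp["excluded"]]
        n_exc = int(grp["excluded"].sum())
        if len(used) == 0:
            rows.append(
                dict(loc_x=lx, loc_y=ly, mse_x=np.nan, mse_y=np.nan,
                     bias_x=np.nan, bias_y=np.nan, n_used=0,
                     n_excluded=n_exc, missing=True)
            )
            continue
        ex = used["x_hat"] - lx
        ey = used["y_hat"] - ly
        rows.append(
            dict(
                loc_x=lx, loc_y=ly,
                mse_x=float(np.mean(ex**2)), mse_y=float(np.mean(ey**2)),
                bias_x=float(np.mean(ex)), bias_y=float(np.mean(ey)),
                n_used=int(len(used)), n_excluded=n_exc, missing=False,
            )
        )
    if not rows:
        raise ValueError("no records")
    return MetricTable(pd.DataFrame(rows))


def region_labels(x_columns: np.ndarray) -> dict:
    """Map each x-column to a region label (close / mid / far).

    The canonical 31-column layout splits 11/10/10; any other layout falls
    back to x-terciles.
    """
    xs = np.sort(np.unique(x_columns))
    n = xs.size
    if n == 31:
        sizes = (11, 10, 10)
    else:
        base, rem = divmod(n, 3)
        sizes = (base + (rem > 0), base + (rem > 1), base)
    labels, i = {}, 0
    for name, s in zip(("close", "mid", "far"), sizes):
        for x in xs[i : i + s]:
            labels[float(x)] = name
        i += s
    return labels


def region_aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Box statistics of per-realization squared x-errors per region."""
    used = records[~records["excluded"]].copy()
    labels = region_labels(used["loc_x"].to_numpy())
    used["region"] = used["loc_x"].map(labels)
    used["se_x"] = (used["x_hat"] - used["loc_x"]) ** 2
    out = []
    for region in ("close", "mid", "far"):
        grp = used[used["region"] == region]
        if len(grp) == 0:
            continue
        se = grp["se_x"].to_numpy()
        out.append(
            dict(
                region=region,
                n_locations=grp.groupby(["loc_x", "loc_y"]).ngroups,
                n_records=len(grp),
                median=float(np.median(se)),
                q25=float(np.percentile(se, 25)),
                q75=float(np.percentile(se, 75)),
                mean=float(np.mean(se)),
            )
        )
    return pd.DataFrame(out)


def random_baseline(prior: PriorBox, locations, n_realizations: int, seed) -> pd.DataFrame:
    """Uniform-in-prior estimates, as a records frame (mechanism 'random')."""
    rng = np.random.default_rng(seed)
    rows = []
    for lx, ly in np.atleast_2d(np.asarray(locations, dtype=float)):
        xs = rng.uniform(prior.x_lo, prior.x_hi, n_realizations)
        ys = rng.uniform(prior.y_lo, prior.y_hi, n_realizations)
        for rep in range(n_realizations):
            rows.append(
                dict(
                    loc_x=lx, loc_y=ly, realization=rep,
                    x_hat=xs[rep], y_hat=ys[rep], mechanism="random",
                    eta=np.nan, theta_hat=np.nan, n_detections=-1,
                    excluded=False,
                )
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# Noise scans
# ---------------------------------------------------------------------------


@dataclass
class TuningCurve:
    """MSEx versus noise level at one test location."""

    x: float
    y: float
    etas: np.ndarray
    mse_x: np.ndarray
    eta_star: float

    @property
    def sigma_star_offset(self) -> float:
        return self.eta_star  # perceived size is radius + eta_star

    def plot(self, ax=None):
        """MSEx against noise level (symlog x), optimum marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.etas, self.mse_x, "o-", ms=4)
        ax.axvline(self.eta_star, ls="--", color="gray")
        ax.set_xscale("symlog")
        ax.set_yscale("log")
        ax.set_xlabel("noise level eta (grid units)")
        ax.set_ylabel("MSEx")
        ax.set_title(f"x={self.x:.0f}, y={self.y:.0f}")
        return ax


def default_eta_grid(radius: float, n: int = 16) -> np.ndarray:
    """0 plus log-spaced levels up to 10 R."""
    return np.concatenate([[0.0], np.geomspace(radius / 10.0, 10.0 * radius, n - 1)])


def optimal_noise_scan(config: ScenarioConfig, etas=None):
    """Scan MSEx over noise levels at every test location.

    Common random numbers: placement and snapshot streams are shared across
    eta values, so curves differ only through the noise draws.  Returns
    ``(curves, records)`` where curves is a list of :class:`TuningCurve`
    (eta_star = argmin MSEx, ties to the smaller eta).
    """
    if etas is None:
        etas = default_eta_grid(config.radius)
    etas = np.asarray(etas, dtype=float)
    if 0.0 not in etas:
        raise ValueError("eta grid must include 0")
    field = config.build_field()
    sampler = config.build_sampler()
    locations = config.test_locations(field)
    mech_idx = MECHANISMS.index(config.mechanism)
    frames = []
    curves = []
    for loc_idx, center in enumerate(locations):
        per_eta_mse = np.empty(etas.size)
        for ei, eta in enumerate(etas):
            recs = [
                _one_realization(
                    config, field, sampler, center, loc_idx, rep,
                    config.mechanism, float(eta), cond_key=mech_idx * 1000 + ei,
                )
                for rep in range(config.n_realizations)
            ]
            df = records_to_frame(recs)
            frames.append(df)
            used = df[~df["excluded"]]
            per_eta_mse[ei] = (
                np.mean((used["x_hat"] - center[0]) ** 2) if len(used) else np.nan
            )
        valid = ~np.isnan(per_eta_mse)
        k = int(np.nanargmin(per_eta_mse)) if valid.any() else 0
        curves.append(
            TuningCurve(float(center[0]), float(center[1]), etas, per_eta_mse, float(etas[k]))
        )
    return curves, pd.concat(frames, ignore_index=True)


def compare_conditions(tables: dict) -> pd.DataFrame:
    """Aggregate per-location MSEx box statistics across named conditions.

    Every condition must cover the same test locations.
    """
    ref_locs = None
    rows = []
    for name, mt in tables.items():
        t = mt.table if isinstance(mt, MetricTable) else mt
        locs = set(zip(t["loc_x"], t["loc_y"]))
        if ref_locs is None:
            ref_locs = locs
        elif locs != ref_locs:
            raise ValueError(f"condition {name!r} uses a different test grid")
        mse = t.loc[~t["missing"], "mse_x"].to_numpy() if "missing" in t else t["mse_x"].to_numpy()
        rows.append(
            dict(
                condition=name,
                median=float(np.median(mse)),
                q25=float(np.percentile(mse, 25)),
                q75=float(np.percentile(mse, 75)),
                mean=float(np.mean(mse)),
                n_locations=int(mse.size),
            )
        )
    return pd.DataFrame(rows)
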