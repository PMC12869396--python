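"""Sensor placement, noise mechanisms, MAP estimation, error correction."""
import numpy as np
import pytest
from scipy import stats

import plumeloc as pl
from plumeloc import (
    NoiseSpec,
    Observation,
    corrected_field,
    corrected_log_likelihood,
    map_argmax,
    map_estimate,
    perceived_size,
    place_sensors,
    single_sensor_timeseries_map,
    truncated_gaussian_noise,
)
from plumeloc.synth import PlumeSampler


class TestPlacement:
    def test_uniform_disc_moments(self):
        """Area-uniform placement: E|offset| = 2R/3."""
        geom = place_sensors([0.0, 0.0], 30.0, 100_000, seed=0)
        r = np.hypot(geom.offsets[:, 0], geom.offsets[:, 1])
        assert r.max() <= 30.0
        assert r.mean() == pytest.approx(2 * 30.0 / 3, rel=0.01)

    def test_single_sensor(self):
        geom = place_sensors([5.0, 5.0], 2.0, 1, seed=1)
        assert geom.offsets.shape == (1, 2)
        assert np.hypot(*geom.offsets[0]) <= 2.0

    def test_reproducible(self):
        a = place_sensors([0, 0], 10.0, 50, seed=7).offsets
        b = place_sensors([0, 0], 10.0, 50, seed=7).offsets
        np.testing.assert_array_equal(a, b)


class TestTruncatedNoise:
    def test_zero_eta_is_zero(self):
        assert (truncated_gaussian_noise(0.0, 10, seed=0) == 0).all()

    def test_moments_match_closed_form(self):
        eta = 25.0
        draws = truncated_gaussian_noise(eta, 100_000, seed=1)
        bound = (eta + 1) / eta
        expect_sd = stats.truncnorm.std(-bound, bound, scale=eta)
        assert draws.std() == pytest.approx(expect_sd, rel=0.01)
        assert np.abs(draws).max() <= eta + 1.0

    def test_perceived_size_additive(self):
        assert perceived_size(25, 0) == 25
        assert perceived_size(25, 25) == 50
        assert perceived_size(10, 74) == 84


@pytest.fixture(scope="module")
def bern_sampler(params):
    return PlumeSampler(params.likelihood)


class TestApplyNoise:
    def _geom(self, n=200, center=(400.0, 0.0)):
        return place_sensors(center, 25.0, n, seed=3)

    def test_zero_eta_matches_noiseless(self, bern_sampler):
        geom = self._geom()
        for mech in pl.MECHANISMS:
            obs = pl.apply_noise(geom, NoiseSpec(mech, 0.0), bern_sampler, seed=5)
            ref = pl.apply_noise(
                geom, NoiseSpec("proprioceptive", 0.0), bern_sampler, seed=5
            )
            np.testing.assert_array_equal(obs.detections, ref.detections)
            np.testing.assert_array_equal(obs.perceived_offsets, geom.offsets)

    def test_proprioceptive_leaves_detections_unchanged(self, bern_sampler):
        """Proprioceptive noise affects processing, not sensing."""
        geom = self._geom()
        noisy = pl.apply_noise(geom, NoiseSpec("proprioceptive", 25.0), bern_sampler, seed=8)
        clean = pl.apply_noise(geom, NoiseSpec("proprioceptive", 0.0), bern_sampler, seed=8)
        np.testing.assert_array_equal(noisy.detections, clean.detections)
        assert not np.array_equal(noisy.perceived_offsets, clean.perceived_offsets)

    def test_flip_half_randomizes(self, params):
        ones = PlumeSampler(lambda pts: np.ones(len(pts)))
        geom = self._geom(n=2000)
        obs = pl.apply_noise(geom, NoiseSpec("flip", 0.5), ones, seed=9)
        assert obs.theta_hat == pytest.approx(0.5, abs=0.05)

    def test_raw_noise_flips_near_threshold(self, params):
        geom = self._geom(n=2000)
        sampler = PlumeSampler(params.likelihood, c0=1.0)
        clean = pl.apply_noise(geom, NoiseSpec("raw", 0.0), sampler, seed=10)
        noisy = pl.apply_noise(geom, NoiseSpec("raw", 5.0), sampler, seed=10)
        assert (clean.detections != noisy.detections).any()

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec("telepathic", 1.0)
        with pytest.raises(ValueError):
            NoiseSpec("flip", 0.7)


class TestMapEstimate:
    def test_single_detecting_sensor_goes_to_near_edge(self, small_field):
        """One detection pulls the estimate to the likelihood maximum."""
        obs = Observation([1], [[0.0, 0.0]])
        rec = map_estimate(obs, small_field, truth=(500.0, 0.0))
        assert rec.estimate[0] == small_field.prior.x_lo
        assert rec.estimate[1] == pytest.approx(0.0, abs=small_field.dy)

    def test_all_zeros_collapse_to_far_edge(self, params):
        """With a centerline-hugging prior, no detections -> far edge (the
        least-likely odor location downwind)."""
        lam = params.lambda_scale
        f = pl.LikelihoodField.from_params(
            params, np.linspace(lam, 15 * lam, 68), np.linspace(-10, 10, 3)
        )
        obs = Observation(np.zeros(50, dtype=int), np.zeros((50, 2)))
        rec = map_estimate(obs, f)
        assert rec.estimate[0] == f.prior.x_hi

    def test_matches_brute_force_posterior(self, small_field):
        """Grid argmax equals exhaustive posterior evaluation, bit-identical."""
        rng = np.random.default_rng(1)
        ci, cj = small_field.prior_node_indices()
        pf = 1e-6
        for _ in range(10):
            n = 25
            det = (rng.random(n) < 0.4).astype(np.uint8)
            per = rng.normal(0, 40, (n, 2))
            obs = Observation(det, per)
            (xh, yh), _ = map_argmax(obs, small_field, pf)
            best = None
            for i, j in zip(ci, cj):
                lp = 0.0
                for s in range(n):
                    ii = int(round((small_field.x[i] + per[s, 0] - small_field.x[0]) / small_field.dx))
                    jj = int(round((small_field.y[j] + per[s, 1] - small_field.y[0]) / small_field.dy))
                    ii = min(max(ii, 0), small_field.x.size - 1)
                    jj = min(max(jj, 0), small_field.y.size - 1)
                    v = min(max(small_field.values[ii, jj], pf), 1 - pf)
                    lp += np.log(v) if det[s] else np.log1p(-v)
                if best is None or lp > best[0] + 1e-12:
                    best = (lp, small_field.x[i], small_field.y[j])
            assert (xh, yh) == (best[1], best[2])

    def test_permutation_invariance(self, small_field):
        rng = np.random.default_rng(2)
        n = 60
        det = (rng.random(n) < 0.3).astype(np.uint8)
        per = rng.normal(0, 30, (n, 2))
        perm = rng.permutation(n)
        a, _ = map_argmax(Observation(det, per), small_field)
        b, _ = map_argmax(Observation(det[perm], per[perm]), small_field)
        assert a == b

    def test_translation_consistency(self, params):
        """Shifting field, prior, and offsets by a lattice vector shifts the argmax."""
        lam = params.lambda_scale
        x = np.linspace(lam, 10 * lam, 60)
        y = np.linspace(-100, 100, 21)
        f1 = pl.LikelihoodField.from_params(params, x, y)
        shift = 5 * f1.dx
        # same physical values, relabeled coordinates
        f2 = pl.LikelihoodField(x + shift, y, f1.values,
                                pl.PriorBox(f1.prior.x_lo + shift, f1.prior.x_hi + shift,
                                            f1.prior.y_lo, f1.prior.y_hi))
        rng = np.random.default_rng(3)
        det = (rng.random(40) < 0.3).astype(np.uint8)
        per = rng.normal(0, 30, (40, 2))
        (x1, y1), _ = map_argmax(Observation(det, per), f1)
        (x2, y2), _ = map_argmax(Observation(det, per), f2)
        assert (x2 - x1, y2 - y1) == (pytest.approx(shift), 0.0)

    def test_estimate_inside_prior_and_exclusion_flag(self, small_field):
        obs = Observation([1, 0], [[0, 0], [5, 5]])
        rec = map_estimate(obs, small_field, min_detections=2)
        assert small_field.prior.contains(np.array(rec.estimate))
        assert rec.excluded
        rec2 = map_estimate(obs, small_field, min_detections=1)
        assert not rec2.excluded

    def test_accuracy_improves_with_sensors_and_radius(self, params, small_field):
        """More sensors help on independent Bernoulli data; a larger radius
        helps on correlated data (it decorrelates the sensors); multisensor
        bias stays below the analytic single-sensor bias."""
        center = np.array([450.0, 0.0])

        def run(sampler, n_sensors, radius, nr, seed=17):
            errs = []
            rng = np.random.default_rng(seed)
            for _ in range(nr):
                geom = place_sensors(center, radius, n_sensors, rng)
                det = sampler.sample(geom.positions, rng)
                rec = map_estimate(Observation(det, geom.offsets), small_field,
                                   truth=center)
                errs.append(rec.estimate[0] - center[0])
            errs = np.asarray(errs)
            return np.mean(errs**2), errs.mean()

        bern = PlumeSampler(params.likelihood)
        mse10, b10 = run(bern, 10, 25.0, 150)
        mse100, b100 = run(bern, 100, 25.0, 150)
        mse500, b500 = run(bern, 500, 25.0, 150)
        assert mse100 <= mse10 * 1.1
        assert mse500 <= mse100 * 1.1
        corr = PlumeSampler(params.likelihood, pl.CorrelationSpec(corr_length=5.0))
        mse_r10, _ = run(corr, 200, 10.0, 250)
        mse_r40, _ = run(corr, 200, 40.0, 250)
        assert mse_r40 <= mse_r10 * 1.1
        # analytic single-sensor bias: two possible outcomes, weighted
        p = float(params.likelihood(center))
        x1 = map_estimate(Observation([1], [[0.0, 0.0]]), small_field).estimate[0]
        x0 = map_estimate(Observation([0], [[0.0, 0.0]]), small_field).estimate[0]
        bias1 = p * (x1 - center[0]) + (1 - p) * (x0 - center[0])
        for b in (b10, b100, b500):
            assert abs(b) < abs(bias1)


class TestSingleSensorTimeseries:
    def test_single_point_equals_map(self, small_field):
        rec_ts = single_sensor_timeseries_map([1], (0.0, 0.0), small_field)
        rec = map_estimate(Observation([1], [[0.0, 0.0]]), small_field)
        assert rec_ts.estimate == rec.estimate

    def test_stride_decorrelates(self, params):
        """MSE at stride >> corr_time matches independent sampling; longer
        series at fixed stride improve the estimate."""
        lam = params.lambda_scale
        x = np.linspace(lam, 8 * lam, 40)
        y = np.linspace(-60, 60, 9)
        field = pl.LikelihoodField.from_params(params, x, y)
        corr = pl.CorrelationSpec(corr_length=0.0, corr_time=5.0)
        truth = np.array([300.0, 0.0])
        node = field.index_of(truth)
        nt, n_rep = 20, 120

        def mse_strided(stride):
            errs = []
            for rep in range(n_rep):
                snaps = pl.sample_correlated(field, corr, nt * stride, seed=1000 + rep)
                series = snaps.binary[:, node[0], node[1]]
                rec = single_sensor_timeseries_map(
                    series, (0.0, 0.0), field, stride=stride, truth=truth
                )
                errs.append(rec.estimate[0] - truth[0])
            return np.mean(np.square(errs))

        def mse_bernoulli(n_points):
            p = field.values[node]
            errs = []
            rng = np.random.default_rng(7)
            for rep in range(n_rep):
                series = (rng.random(n_points) < p).astype(int)
                rec = single_sensor_timeseries_map(series, (0.0, 0.0), field, truth=truth)
                errs.append(rec.estimate[0] - truth[0])
            return np.mean(np.square(errs))

        m1, m15 = mse_strided(1), mse_strided(15)
        m_indep = mse_bernoulli(nt)
        assert m15 <= m1 * 1.05  # decorrelation cannot hurt
        assert m15 == pytest.approx(m_indep, rel=0.45)  # plateau matches bootstrap
        assert mse_bernoulli(100) < m_indep  # longer series helps


class TestCorrection:
    def test_zero_eta_identity(self, small_field):
        for mech in pl.MECHANISMS:
            cf = corrected_field(small_field, NoiseSpec(mech, 0.0))
            np.testing.assert_allclose(cf.values, small_field.values)

    def test_flip_formula_and_fixed_point(self, small_field):
        eta0 = 0.01
        cf = corrected_field(small_field, NoiseSpec("flip", eta0))
        np.testing.assert_allclose(cf.values, eta0 + (1 - 2 * eta0) * small_field.values)
        assert 0.01 + 0.98 * 0.344 == pytest.approx(0.34712)
        # l = 0.5 is a fixed point of the flip correction for any eta0
        half = pl.LikelihoodField(small_field.x, small_field.y,
                                  np.full(small_field.shape, 0.5), small_field.prior)
        for e in (0.05, 0.2, 0.4):
            np.testing.assert_allclose(
                corrected_field(half, NoiseSpec("flip", e)).values, 0.5
            )

    def test_flip_nonidentifiable(self, small_field):
        with pytest.raises(ValueError):
            corrected_field(small_field, NoiseSpec("flip", 0.5))

    def test_blur_small_eta_recovers_field(self, small_field):
        cf = corrected_field(small_field, NoiseSpec("proprioceptive", 1e-4))
        np.testing.assert_allclose(cf.values, small_field.values, atol=1e-6)

    def test_blur_smooths(self, small_field):
        cf = corrected_field(small_field, NoiseSpec("positional", 40.0))
        # smoothing reduces the lateral gradient magnitude
        g0 = np.abs(np.diff(small_field.values, axis=1)).max()
        g1 = np.abs(np.diff(cf.values, axis=1)).max()
        assert g1 < g0
        assert cf.values.min() >= 0 and cf.values.max() <= 1

    def test_surface_matches_uncorrected_at_zero(self, small_field):
        rng = np.random.default_rng(5)
        det = (rng.random(30) < 0.3).astype(np.uint8)
        obs = Observation(det, rng.normal(0, 20, (30, 2)))
        _, lp0, am0 = corrected_log_likelihood(obs, small_field, NoiseSpec("flip", 0.0))
        (xh, yh), lp = map_argmax(obs, small_field)
        np.testing.assert_allclose(lp0, lp)
        assert am0 == (xh, yh)
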