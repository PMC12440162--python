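import numpy as np
import pytest

from hiveflow import (fit_var, ipdc_spectrum, information_flow, simulate_var,
                      social_influence, InfluenceSettings)
from hiveflow.influence import IpdcSpectrum, VarModel, InfluenceFitError
from hiveflow.proximity import ProximityInteraction


def model_from(coef, sigma=None, k=2):
    coef = np.asarray(coef, dtype=float)
    if coef.ndim == 2:
        coef = coef[None, :, :]
    return VarModel(order=coef.shape[0], coef=coef,
                    sigma=np.eye(k) if sigma is None else np.asarray(sigma, float),
                    n_obs=1000, n_eff=999)


def random_stable_var(rng, k=2, p=2, radius_cap=0.95, scale=0.4):
    while True:
        A = rng.normal(0, scale, (p, k, k))
        top = np.hstack(list(A))
        comp = top if p == 1 else np.vstack(
            [top, np.hstack([np.eye(k * (p - 1)), np.zeros((k * (p - 1), k))])])
        if np.max(np.abs(np.linalg.eigvals(comp))) < radius_cap:
            return A


class TestFitVar:
    def test_recovers_generating_coefficients(self):
        A = np.array([[0.5, 0.0], [0.3, 0.5]])
        x = simulate_var([A], np.eye(2), 50_000, seed=42)
        m = fit_var(x, order=1)
        np.testing.assert_allclose(m.coef[0], A, atol=0.02)
        np.testing.assert_allclose(m.sigma, np.eye(2), atol=0.05)

    def test_white_noise_null(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20_000, 2))
        m = fit_var(x, order=1)
        np.testing.assert_allclose(m.coef[0], 0.0, atol=0.05)

    def test_constant_series_raises(self):
        with pytest.raises(ValueError, match="constant|singular"):
            fit_var((np.ones(50), np.arange(50.0)), order=1)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="short"):
            fit_var(np.random.default_rng(0).standard_normal((7, 2)), order=3)

    def test_matches_statsmodels_var(self):
        # independent estimator cross-check on the same centered series
        from statsmodels.tsa.api import VAR as SmVAR

        x = simulate_var([np.array([[0.4, 0.1], [0.2, 0.3]])], np.eye(2), 2_000, seed=7)
        xc = x - x.mean(axis=0)
        ours = fit_var(xc, order=2)
        ref = SmVAR(xc).fit(2, trend="n")
        np.testing.assert_allclose(ours.coef[0], ref.coefs[0], atol=1e-8)
        np.testing.assert_allclose(ours.coef[1], ref.coefs[1], atol=1e-8)
        np.testing.assert_allclose(ours.sigma, ref.sigma_u, rtol=1e-2)

    def test_order_selection_prefers_true_order(self):
        A = random_stable_var(np.random.default_rng(5), p=2, scale=0.45)
        x = simulate_var(list(A), np.eye(2), 5_000, seed=8)
        m = fit_var(x, order="aic", p_max=3)
        assert m.order >= 2


class TestIpdcSpectrum:
    def test_absent_direction_is_zero(self):
        # lower-triangular coefficients: channel 2 never enters channel 1
        m = model_from([[0.5, 0.0], [0.3, 0.5]])
        spec = ipdc_spectrum(m, n_freqs=64)
        np.testing.assert_allclose(spec.direction(1, 0), 0.0, atol=1e-15)

    def test_hand_computed_point_at_zero_frequency(self):
        # Abar(0) = [[0.5, 0], [-0.3, 0.5]]; direction 1->2:
        # |Abar_21|^2 / (Sigma_22 * ||abar_1||^2) = 0.09 / 0.34
        m = model_from([[0.5, 0.0], [0.3, 0.5]])
        spec = ipdc_spectrum(m, n_freqs=64)
        assert spec.freqs[0] == 0.0
        assert spec.direction(0, 1)[0] == pytest.approx(0.09 / 0.34, abs=1e-12)

    def test_classic_pdc_column_normalization(self):
        rng = np.random.default_rng(2)
        A = random_stable_var(rng, p=3)
        m = VarModel(order=3, coef=A, sigma=np.diag([1.0, 2.5]), n_obs=100, n_eff=97)
        spec = ipdc_spectrum(m, n_freqs=33, variant="euc")
        col_sums = spec.values.sum(axis=0)   # sum over targets i, per source j
        np.testing.assert_allclose(col_sums, 1.0, atol=1e-12)

    def test_info_reduces_to_generalized_for_diagonal_sigma(self):
        rng = np.random.default_rng(3)
        A = random_stable_var(rng, p=2)
        m = VarModel(order=2, coef=A, sigma=np.diag([0.5, 3.0]), n_obs=100, n_eff=98)
        info = ipdc_spectrum(m, n_freqs=50, variant="info")
        gpdc = ipdc_spectrum(m, n_freqs=50, variant="diag")
        np.testing.assert_allclose(info.values, gpdc.values, atol=1e-12)

    def test_bounded_on_random_stable_models(self):
        # 1,000 random stable VAR(1..3) models with random SPD innovation
        # covariance: every squared iPDC value must lie in [0, 1]
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            p = int(rng.integers(1, 4))
            A = random_stable_var(rng, p=p)
            L = rng.normal(0, 1, (2, 2))
            sigma = L @ L.T + 0.05 * np.eye(2)
            m = VarModel(order=p, coef=A, sigma=sigma, n_obs=100, n_eff=100 - p)
            spec = ipdc_spectrum(m, n_freqs=17)
            assert np.all(spec.values >= -1e-12)
            assert np.all(spec.values <= 1.0 + 1e-9)

    def test_singular_sigma_raises(self):
        m = model_from([[0.5, 0.0], [0.3, 0.5]], sigma=[[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="singular"):
            ipdc_spectrum(m)


class TestInformationFlow:
    def test_zero_spectrum_zero_bits(self):
        freqs = np.linspace(0, 0.5, 64)
        assert information_flow(np.zeros(64), freqs=freqs, fs=1.0) == 0.0

    def test_constant_half_spectrum(self):
        freqs = np.linspace(0, 0.5, 128)
        flow = information_flow(np.full(128, 0.5), freqs=freqs, fs=1.0)
        assert flow == pytest.approx(0.5, abs=1e-3)

    def test_constant_three_quarters_at_fs2(self):
        freqs = np.linspace(0, 1.0, 128)
        flow = information_flow(np.full(128, 0.75), freqs=freqs, fs=2.0)
        assert flow == pytest.approx(1.0, abs=1e-3)

    def test_invalid_spectrum_raises(self):
        freqs = np.linspace(0, 0.5, 8)
        with pytest.raises(ValueError, match="invalid"):
            information_flow(np.full(8, 1.5), freqs=freqs, fs=1.0)

    def test_nonnegative_and_zero_iff_zero(self):
        rng = np.random.default_rng(1)
        m = VarModel(order=1, coef=random_stable_var(rng, p=1), sigma=np.eye(2),
                     n_obs=100, n_eff=99)
        spec = ipdc_spectrum(m, n_freqs=64)
        for src, dst in ((0, 1), (1, 0)):
            flow = information_flow(spec, direction=(src, dst))
            assert flow >= 0.0
            if np.any(spec.direction(src, dst) > 0):
                assert flow > 0.0

    def test_grid_doubling_converged(self):
        m = model_from([[0.5, 0.0], [0.3, 0.5]])
        f1 = information_flow(ipdc_spectrum(m, n_freqs=128), direction=(0, 1))
        f2 = information_flow(ipdc_spectrum(m, n_freqs=256), direction=(0, 1))
        assert abs(f1 - f2) < 1e-3


class TestFittedVsTrueSpectrum:
    def test_oracle_equivalence_on_random_var2_models(self):
        # spectrum from a model fitted to 10,000 samples vs the spectrum of
        # the true generating coefficients, 20 random stable bivariate VAR(2)
        rng = np.random.default_rng(2024)
        worst = 0.0
        for i in range(20):
            A = random_stable_var(rng, p=2)
            x = simulate_var(list(A), np.eye(2), 10_000, seed=9000 + i)
            fitted = fit_var(x, order=2)
            true_m = VarModel(order=2, coef=A, sigma=np.eye(2), n_obs=0, n_eff=0)
            sf = ipdc_spectrum(fitted, n_freqs=64)
            st_ = ipdc_spectrum(true_m, n_freqs=64)
            worst = max(worst, float(np.max(np.abs(sf.values - st_.values))))
        assert worst < 0.05


def _interaction(series_a, series_b):
    n = len(series_a)
    return ProximityInteraction(
        focal_id=0, neighbor_id=1, start_frame=0, end_frame=n - 1,
        focal_x=np.asarray(series_a, float), focal_y=np.asarray(series_a, float) + 1.0,
        neighbor_x=np.asarray(series_b, float), neighbor_y=np.asarray(series_b, float) - 1.0)


class TestSocialInfluence:
    def _random_interaction(self, seed, n=40):
        rng = np.random.default_rng(seed)
        a = np.cumsum(rng.normal(0, 5, n)) + 100
        b = np.cumsum(rng.normal(0, 5, n)) + 100
        return _interaction(a, b)

    def test_single_interaction_is_identity(self):
        it = self._random_interaction(0)
        r1 = social_influence(0, [it])
        r2 = social_influence(0, [it, it])
        assert r1.i_flow_out == pytest.approx(r2.i_flow_out)
        assert r1.i_flow_in == pytest.approx(r2.i_flow_in)
        assert r2.n_interactions == 2

    def test_final_flow_is_mean_of_axes(self):
        r = social_influence(0, [self._random_interaction(1)])
        assert r.i_flow_out == pytest.approx(np.mean([r.out_by_axis["X"], r.out_by_axis["Y"]]))
        assert r.i_flow_out >= 0 and r.i_flow_in >= 0

    def test_all_failures_raise_with_diagnostics(self):
        flat = _interaction(np.ones(40), np.ones(40) * 2)
        with pytest.raises(InfluenceFitError) as exc:
            social_influence(7, [flat])
        assert exc.value.diagnostics

    def test_no_interactions_raises(self):
        with pytest.raises(ValueError):
            social_influence(0, [])
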