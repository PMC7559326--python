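"""Adsorption models: identities, reductions, fitting and recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfilm.exceptions import DomainError, ValidationError
from surfilm.isotherms import (BETIsotherm, IsothermSeries, SipsIsotherm,
                               bet_coverage, confidence_intervals,
                               coverage_from_theta, fit_isotherm,
                               half_saturation, langmuir_theta, sips_theta)


class TestModelFunctions:
    def test_langmuir_half_saturation_identity(self):
        assert langmuir_theta(1 / 0.3, 0.3) == pytest.approx(0.5)
        assert langmuir_theta(0.0, 0.3) == 0.0

    def test_langmuir_saturates_monotonically(self):
        c = np.geomspace(1e-3, 1e5, 60)
        th = langmuir_theta(c, 1.0)
        assert np.all(np.diff(th) > 0) and th[-1] > 0.9999

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(conc=st.floats(1e-6, 1e3), K=st.floats(1e-3, 1e3))
    def test_sips_reduces_to_langmuir_at_n_one(self, conc, K):
        assert sips_theta(conc, K, 1.0) == pytest.approx(
            langmuir_theta(conc, K), rel=1e-12)

    def test_sips_hand_value(self):
        # n=0.5, K=1, c=4: theta = 2/(1+2)
        assert sips_theta(4.0, 1.0, 0.5) == pytest.approx(2.0 / 3.0)

    def test_sips_half_saturation_at_cn_equals_inv_K(self):
        K, n = 0.25, 0.6
        c = (1 / K) ** (1 / n)
        assert sips_theta(c, K, n) == pytest.approx(0.5)

    def test_heterogeneity_index_capped_without_override(self):
        with pytest.raises(ValidationError):
            sips_theta(1.0, 1.0, 1.5)
        assert sips_theta(1.0, 1.0, 1.5, allow_hill=True) > 0

    def test_coverage_from_theta_bsa_saturation_fixture(self):
        # Q*m_a chosen so full occupancy gives the 450 ng/cm^2 plateau
        m_a = 66_500.0
        Q = 450e-9 / m_a * 6.02214076e23 * 1e-14  # sites per nm^2
        assert coverage_from_theta(1.0, Q, m_a) == pytest.approx(450.0)
        assert coverage_from_theta(0.0, Q, m_a) == 0.0
        assert coverage_from_theta(0.5, Q, m_a) == pytest.approx(225.0)

    def test_bet_reduces_to_langmuir_without_multilayer(self):
        c = np.geomspace(1e-4, 10, 30)
        full = bet_coverage(c, 2.0, 5.0, 0.0)
        mono = 2.0 * 5.0 * c / (1 + 5.0 * c)
        assert np.allclose(full, mono, rtol=1e-12)
        assert bet_coverage(0.0, 2.0, 5.0, 0.5) == 0.0

    def test_bet_low_concentration_slope(self):
        q1, K_L = 3.0, 50.0
        c = 1e-6 / K_L
        assert bet_coverage(c, q1, K_L, 1.0) / c == pytest.approx(q1 * K_L, rel=0.01)

    def test_bet_divergence_is_a_domain_error(self):
        with pytest.raises(DomainError):
            bet_coverage(2.0, 1.0, 10.0, 0.5)

    def test_isotherms_vanish_at_zero_and_increase(self):
        c = np.geomspace(1e-4, 1.0, 40)
        for y in (langmuir_theta(c, 3.0), sips_theta(c, 3.0, 0.7),
                  bet_coverage(c, 1.0, 30.0, 0.9)):
            assert np.all(y >= 0) and np.all(np.diff(y) > 0)


class TestFitting:
    conc_uM = np.geomspace(1.0, 200.0, 10)
    truth = dict(K=0.1, n=0.7, gamma_sat=450.0)

    def _sips_y(self):
        return self.truth["gamma_sat"] * sips_theta(
            self.conc_uM, self.truth["K"], self.truth["n"])

    def test_noiseless_sips_recovery_is_exact(self):
        fit = fit_isotherm(IsothermSeries(self.conc_uM, self._sips_y(),
                                          conc_unit="uM"), "sips")
        assert fit.K == pytest.approx(self.truth["K"], rel=1e-3)
        assert fit.n_het == pytest.approx(self.truth["n"], rel=1e-3)
        assert fit.gamma_sat == pytest.approx(self.truth["gamma_sat"], rel=1e-3)

    def test_noiseless_bet_recovery_is_exact(self):
        c = np.geomspace(0.005, 0.18, 10)
        y = bet_coverage(c, 12.0, 100.0, 3.55)
        fit = fit_isotherm(IsothermSeries(c, y, response_kind="volume_coverage"),
                           "bet")
        assert fit.q1 == pytest.approx(12.0, rel=1e-3)
        assert fit.K_L == pytest.approx(100.0, rel=1e-3)
        assert fit.K_ml == pytest.approx(3.55, rel=1e-3)

    def test_grid_search_oracle_brackets_same_sips_optimum(self):
        y = self._sips_y()
        Ks = np.geomspace(0.01, 1.0, 40)
        ns = np.linspace(0.3, 1.0, 30)
        best, best_sse = None, np.inf
        for K in Ks:
            for n in ns:
                model = 450.0 * sips_theta(self.conc_uM, K, n)
                sse = np.sum((model - y) ** 2)
                if sse < best_sse:
                    best, best_sse = (K, n), sse
        fit = fit_isotherm(IsothermSeries(self.conc_uM, y, conc_unit="uM"), "sips")
        # the coarse-lattice optimum must bracket the fitted optimum
        assert abs(np.log(fit.K / best[0])) < np.log(Ks[1] / Ks[0]) * 1.5
        assert abs(fit.n_het - best[1]) < (ns[1] - ns[0]) * 1.5

    def test_monte_carlo_bias_and_ci_coverage(self):
        """5% multiplicative noise, 200 replicates: bias < 10% per parameter
        and 95% t-intervals cover each truth 90-99% of the time."""
        y0 = self._sips_y()
        rng = np.random.default_rng(7)
        true = np.array([self.truth["K"], self.truth["n"], self.truth["gamma_sat"]])
        est, covered = [], np.zeros(3)
        for rep in range(200):
            y = np.clip(y0 * (1 + 0.05 * rng.standard_normal(y0.shape)), 1e-9, None)
            series = IsothermSeries(self.conc_uM, y, conc_unit="uM", sigma=0.05 * y)
            fit = fit_isotherm(series, "sips", random_state=rep)
            est.append([fit.K, fit.n_het, fit.gamma_sat])
            ci = confidence_intervals(fit)
            for j, name in enumerate(("K", "n_het", "gamma_sat")):
                lo, hi = ci[name]
                covered[j] += lo <= true[j] <= hi
        bias = np.abs(np.mean(est, axis=0) - true) / true
        assert np.all(bias < 0.10)
        assert np.all((covered / 200 >= 0.90) & (covered / 200 <= 0.99))

    def test_bet_on_langmuir_data_finds_no_multilayer(self):
        c = np.geomspace(0.005, 0.18, 10)
        y = 10.0 * 50.0 * c / (1 + 50.0 * c)
        rng = np.random.default_rng(11)
        y = np.clip(y * (1 + 0.02 * rng.standard_normal(y.shape)), 1e-9, None)
        fit = fit_isotherm(IsothermSeries(c, y), "bet")
        lo, hi = confidence_intervals(fit)["K_ml"]
        assert lo <= 0.0 <= hi or fit.K_ml < 1e-6

    def test_aic_reported_and_deterministic(self):
        series = IsothermSeries(self.conc_uM, self._sips_y(), conc_unit="uM")
        f1 = fit_isotherm(series, "sips", random_state=3)
        f2 = fit_isotherm(series, "sips", random_state=3)
        assert np.isfinite(f1.aic) and f1.K == f2.K and f1.aic == f2.aic

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_isotherm(IsothermSeries([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), "sips")

    def test_estimators_follow_sklearn_protocol(self):
        from sklearn.base import clone
        est = SipsIsotherm(random_state=5)
        assert clone(est).get_params()["random_state"] == 5
        est.fit(self.conc_uM.reshape(-1, 1), self._sips_y())
        pred = est.predict(self.conc_uM.reshape(-1, 1))
        assert np.allclose(pred, self._sips_y(), rtol=1e-6)
        assert set(est.params_) == {"K", "n_het", "gamma_sat"}
        assert BETIsotherm().get_params()["n_starts"] == 5


class TestHalfSaturation:
    def test_langmuir_case_reproduces_inverse_affinity(self):
        from surfilm.isotherms import SipsFit
        fit = SipsFit(K=1 / 12.0, n_het=1.0, gamma_sat=450.0)
        assert half_saturation(fit) == pytest.approx(12.0)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(K=st.floats(1e-3, 1e3), n=st.floats(0.2, 1.0))
    def test_theta_at_half_saturation_is_half(self, K, n):
        from surfilm.isotherms import SipsFit
        c_half = half_saturation(SipsFit(K=K, n_het=n, gamma_sat=1.0))
        assert sips_theta(c_half, K, n) == pytest.approx(0.5, rel=1e-9)

    def test_sublinear_heterogeneity_hand_value(self):
        from surfilm.isotherms import SipsFit
        assert half_saturation(SipsFit(K=1.0, n_het=0.5, gamma_sat=1.0)) == 1.0
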