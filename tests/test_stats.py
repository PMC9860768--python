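"""Impaction parameter, semi-empirical correlation, and sigmoid fitting."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aerodep as ad
from aerodep.stats import FitError, UNIT_LPM, UNIT_MLS


class TestImpactionParameter:
    @pytest.mark.parametrize("d_um,q_lpm,expected", [
        (1.0, 18.0, 18.0), (10.0, 18.0, 1800.0), (10.0, 45.0, 4500.0)])
    def test_values_in_lpm_system(self, d_um, q_lpm, expected):
        assert ad.impaction_parameter(d_um, q_lpm) == expected

    def test_unit_conversion(self):
        """18 um^2 L/min = 300 um^2 mL/s."""
        assert ad.convert_impaction(18.0, UNIT_LPM, UNIT_MLS) \
            == pytest.approx(300.0, rel=1e-15)
        x = 123.4
        back = ad.convert_impaction(
            ad.convert_impaction(x, UNIT_LPM, UNIT_MLS), UNIT_MLS, UNIT_LPM)
        assert back == pytest.approx(x, rel=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ad.impaction_parameter(-1.0, 18.0)
        with pytest.raises(ValueError):
            ad.convert_impaction(1.0, "um2_lpm", "furlongs")


class TestStahlhofen:
    def test_limits(self):
        assert ad.stahlhofen_eta(x=1e-6) < 1e-6
        assert ad.stahlhofen_eta(x=1e12) > 0.999999
        assert 0 < ad.stahlhofen_eta(5.0, 300.0) < 1

    def test_value_against_arbitrary_precision(self):
        """d_a = 5 um, Q = 300 mL/s against a sympy high-precision oracle."""
        import sympy
        x = sympy.Rational(25) * 300
        eta = 1 - 1 / (sympy.Rational(35, 10 ** 9) * x ** sympy.Rational(17, 10) + 1)
        expected = float(sympy.N(eta, 30))
        assert ad.stahlhofen_eta(5.0, 300.0) == pytest.approx(
            expected, rel=1e-10)

    @given(st.floats(min_value=1.0, max_value=1e7),
           st.floats(min_value=1.001, max_value=10.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_increasing(self, x, factor):
        assert ad.stahlhofen_eta(x=x * factor) > ad.stahlhofen_eta(x=x)


class TestRegionalDe:
    def test_laryngeal_percentage(self):
        """2,071 of 10,000 trapped in the larynx is a 20.71% DE."""
        res = ad.DepositionResult(
            n_injected=10_000, n_region={"LARYNX": 2071}, n_escaped=7929,
            n_lost=0, d_um=10.0, flow_lpm=18.0, direction="inspiratory")
        des = ad.regional_de(res)
        assert des["LARYNX"] == pytest.approx(20.71)
        assert des["total"] == pytest.approx(20.71)

    def test_all_escaped_and_all_trapped(self):
        escaped = ad.DepositionResult(
            n_injected=100, n_region={}, n_escaped=100, n_lost=0,
            d_um=1.0, flow_lpm=18.0, direction="inspiratory")
        assert ad.regional_de(escaped)["total"] == 0.0
        trapped = ad.DepositionResult(
            n_injected=100, n_region={"MOUTH": 100}, n_escaped=0, n_lost=0,
            d_um=30.0, flow_lpm=45.0, direction="inspiratory")
        des = ad.regional_de(trapped)
        assert des["MOUTH"] == des["total"] == 100.0


class TestSigmoidFit:
    def test_recovers_generating_correlation(self):
        """Noise-free data from the semi-empirical correlation returns its
        own constants to 4 significant digits with R^2 = 1."""
        x = np.logspace(2, 6, 50)
        fit = ad.fit_sigmoid(x, ad.stahlhofen_eta(x=x))
        assert fit.beta1 == pytest.approx(3.5e-8, rel=1e-4)
        assert fit.beta2 == pytest.approx(1.7, rel=1e-4)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert not fit.flagged

    def test_recovers_alternative_constants(self):
        """Recovery also holds for the reported best-fit parameter pair."""
        x = np.logspace(2, 6, 50)
        de = 1.0 - 1.0 / (6.73e-8 * x ** 1.65 + 1.0)
        fit = ad.fit_sigmoid(x, de)
        assert fit.beta1 == pytest.approx(6.73e-8, rel=1e-4)
        assert fit.beta2 == pytest.approx(1.65, rel=1e-4)

    def test_unit_equivariance(self):
        """Refitting in the other unit system scales beta1 by exactly
        (1000/60)^beta2 and leaves beta2 and R^2 unchanged."""
        rng = np.random.default_rng(3)
        x_mls = np.logspace(2.5, 5.5, 60)
        de = np.clip(ad.stahlhofen_eta(x=x_mls)
                     + rng.normal(0, 0.02, x_mls.size), 0.001, 0.999)
        f_mls = ad.fit_sigmoid(x_mls, de, x_unit=UNIT_MLS)
        x_lpm = ad.convert_impaction(x_mls, UNIT_MLS, UNIT_LPM)
        f_lpm = ad.fit_sigmoid(x_lpm, de, x_unit=UNIT_LPM)
        c = (1000.0 / 60.0) ** f_mls.beta2
        assert f_lpm.beta2 == pytest.approx(f_mls.beta2, rel=1e-10)
        assert f_lpm.r2 == pytest.approx(f_mls.r2, rel=1e-10)
        assert f_lpm.beta1 / f_mls.beta1 == pytest.approx(c, rel=1e-10)

    def test_ci_covers_truth_on_noisy_data(self):
        rng = np.random.default_rng(7)
        x = np.logspace(2, 6, 200)
        eta = ad.stahlhofen_eta(x=x)
        lg = np.log(eta / (1 - eta)) + rng.normal(0, 0.3, x.size)
        fit = ad.fit_sigmoid(x, 1.0 / (1.0 + np.exp(-lg)))
        assert fit.ci_beta2[0] <= 1.7 <= fit.ci_beta2[1]
        assert fit.ci_beta1[0] <= 3.5e-8 <= fit.ci_beta1[1]

    def test_single_decade_input_is_flagged(self):
        """Identifiability failure is surfaced, never silently confident."""
        rng = np.random.default_rng(0)
        x = np.logspace(3, 3.9, 12)
        eta = ad.stahlhofen_eta(x=x)
        lg = np.log(eta / (1 - eta)) + rng.normal(0, 0.3, x.size)
        try:
            fit = ad.fit_sigmoid(x, 1.0 / (1.0 + np.exp(-lg)))
            assert fit.flagged
        except FitError:
            pass

    def test_zero_de_points_are_retained(self):
        """Exact zeros stay in the least-squares fit (no logit dropout)."""
        x = np.logspace(2, 6, 30)
        de = ad.stahlhofen_eta(x=x)
        de[:3] = 0.0
        fit = ad.fit_sigmoid(x, de)
        assert fit.n == 30

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ad.fit_sigmoid(np.array([1e3, 1e4]), np.array([0.1, 0.5]))

    def test_impaction_point_list_interface(self):
        pts = [ad.ImpactionPoint(d_um=d, q_lpm=18.0,
                                 de_percent=100 * float(
                                     ad.stahlhofen_eta(d, 300.0)))
               for d in (1, 2, 4, 8, 16, 32, 64)]
        fit = ad.fit_sigmoid(pts)
        assert fit.beta2 == pytest.approx(1.7, rel=1e-3)
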