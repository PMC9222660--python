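import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aslt.constants import H_PLANCK, K_BOLTZMANN, R_GAS
from aslt.errors import DomainError, InsufficientDataError
from aslt.thermal import (
    ArrheniusFit,
    EyringConvention,
    FitForm,
    RatePoint,
    compute_tref,
    entropy_from_point,
    fit_arrhenius,
    fit_eyring,
    predict_rate,
)
from conftest import ols_line

TEMPS = (298.15, 308.15, 318.15)


def arrhenius_points(A, Ea, temps=TEMPS):
    return [RatePoint(T, A * np.exp(-Ea / (R_GAS * T))) for T in temps]


class TestTref:
    @pytest.mark.parametrize(
        "temps,expected",
        [(TEMPS, 308.15), ((300.0,), 300.0), ((298.15, 318.15), 308.15)],
    )
    def test_arithmetic_mean(self, temps, expected):
        assert compute_tref(temps) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_tref([])


class TestArrhenius:
    def test_flat_rates_give_zero_activation_energy(self):
        pts = [RatePoint(T, 0.5) for T in TEMPS]
        f = fit_arrhenius(pts)
        assert f.Ea == pytest.approx(0.0, abs=1e-9)
        assert f.kref_at_Tref == pytest.approx(0.5)
        assert f.A_classic == pytest.approx(0.5)

    def test_noiseless_inversion_recovers_parameters(self):
        f = fit_arrhenius(arrhenius_points(3.412e10, 70070.0))
        assert f.Ea == pytest.approx(70070.0, rel=1e-6)
        assert f.A_classic == pytest.approx(3.412e10, rel=1e-6)

    def test_printed_radish_lightness_triple_matches_ols_oracle(self):
        """Refit of the printed per-temperature rate triple; the expected Ea is
        the closed-form OLS of ln k on 1/T."""
        ks = [0.0424, 0.1035, 0.2276]
        pts = [RatePoint(T, k) for T, k in zip(TEMPS, ks)]
        f = fit_arrhenius(pts)
        slope, _ = ols_line([1 / T for T in TEMPS], np.log(ks))
        assert f.Ea == pytest.approx(-slope * R_GAS, rel=1e-10)
        assert f.Ea == pytest.approx(66.29e3, rel=1e-3)

    def test_negative_rate_uses_magnitude(self):
        f_pos = fit_arrhenius(arrhenius_points(1.076e6, 47230.0))
        pts_neg = [RatePoint(p.temperature_K, -p.k) for p in arrhenius_points(1.076e6, 47230.0)]
        f_neg = fit_arrhenius(pts_neg)
        assert f_neg.Ea == pytest.approx(f_pos.Ea, rel=1e-12)

    def test_single_temperature_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_arrhenius([RatePoint(300.0, 0.1), RatePoint(300.0, 0.2)])

    def test_nonlinear_form_agrees_on_noiseless_data(self):
        f = fit_arrhenius(arrhenius_points(1.147e10, 65180.0), form=FitForm.NONLINEAR)
        assert f.Ea == pytest.approx(65180.0, rel=1e-6)

    def test_synthetic_recovery_under_lognormal_noise(self):
        """Ea recovered within 10% in >=95% of 500 seeded replicates with 5%
        multiplicative noise at three temperatures."""
        A, Ea = 3.412e10, 70070.0
        ok = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            pts = [
                RatePoint(T, k * rng.lognormal(0.0, 0.05))
                for T, k in ((p.temperature_K, p.k) for p in arrhenius_points(A, Ea))
            ]
            f = fit_arrhenius(pts)
            ok += abs(f.Ea - Ea) / Ea < 0.10
        assert ok >= 475


class TestEyring:
    def test_rate_proportional_to_temperature_gives_zero_enthalpy(self):
        c = 1e-3
        pts = [RatePoint(T, c * T) for T in TEMPS]
        f = fit_eyring(pts)
        assert f.dH == pytest.approx(0.0, abs=1e-6)
        assert f.dS == pytest.approx(
            R_GAS * (np.log(c) - np.log(K_BOLTZMANN / H_PLANCK)), rel=1e-9
        )

    def test_printed_triple_matches_ols_oracle(self):
        ks = np.array([0.0424, 0.1035, 0.2276])
        temps = np.array(TEMPS)
        pts = [RatePoint(T, k) for T, k in zip(temps, ks)]
        f = fit_eyring(pts)
        slope, intercept = ols_line(1 / temps, np.log(ks / temps))
        assert f.dH == pytest.approx(-slope * R_GAS, rel=1e-10)
        assert f.dS == pytest.approx(
            R_GAS * (intercept - np.log(K_BOLTZMANN / H_PLANCK)), rel=1e-10
        )
        assert f.dH == pytest.approx(63.7e3, rel=2e-3)
        assert f.dS == pytest.approx(-57.4, abs=0.1)

    def test_single_point_entropy_reconstruction(self):
        """ΔS* from the printed ΔH* and the 35 °C rate under the per-day
        convention reproduces the printed −60.98 J/(mol·K)."""
        ds = entropy_from_point(dH=62.60e3, k=0.1035, T=308.15)
        assert ds == pytest.approx(-60.98, rel=5e-3)

    def test_si_convention_shifts_entropy_by_log_day(self):
        pts = arrhenius_points(1.147e10, 65180.0)
        day = fit_eyring(pts, EyringConvention.DAY)
        si = fit_eyring(pts, EyringConvention.SI)
        assert day.dH == pytest.approx(si.dH, rel=1e-12)
        assert day.dS - si.dS == pytest.approx(R_GAS * np.log(86400.0), rel=1e-12)

    def test_enthalpy_close_to_arrhenius_energy_minus_RT(self):
        """ΔH* ≈ Ea − R·T̄ on the study's temperature span (within 2%)."""
        pts = arrhenius_points(9.673e9, 58100.0)
        ea = fit_arrhenius(pts).Ea
        dh = fit_eyring(pts).dH
        tbar = compute_tref(TEMPS)
        assert dh == pytest.approx(ea - R_GAS * tbar, rel=0.02)


class TestPredictRate:
    def test_reference_point_returns_kref(self):
        f = fit_arrhenius(arrhenius_points(3.412e10, 70070.0), Tref_K=308.15)
        assert predict_rate(f, 308.15) == pytest.approx(f.kref_at_Tref, rel=1e-12)

    def test_direct_evaluation_at_45C(self):
        """k(318.15 K) for the sensory model ≈ 0.1069 d⁻¹ (direct closed form)."""
        f = fit_arrhenius(arrhenius_points(3.412e10, 70070.0))
        assert predict_rate(f, 318.15) == pytest.approx(
            3.412e10 * np.exp(-70070.0 / (R_GAS * 318.15)), rel=1e-10
        )
        assert predict_rate(f, 318.15) == pytest.approx(0.1069, abs=2e-4)

    def test_eyring_prediction_reproduces_input_rates(self):
        pts = arrhenius_points(1.147e10, 65180.0)
        f = fit_eyring(pts)
        for p in pts:
            assert predict_rate(f, p.temperature_K) == pytest.approx(p.k, rel=1e-2)

    def test_nonpositive_temperature_rejected(self):
        f = fit_arrhenius(arrhenius_points(1e8, 50000.0))
        with pytest.raises(DomainError):
            predict_rate(f, 0.0)


class TestParameterizationIdentity:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        logA=st.floats(2.0, 26.0),
        Ea=st.floats(1e3, 1.2e5),
        T=st.floats(260.0, 360.0),
    )
    def test_centered_and_classic_forms_agree(self, logA, Ea, T):
        A = float(np.exp(logA))
        f = fit_arrhenius(arrhenius_points(A, Ea))
        classic = f.A_classic * np.exp(-f.Ea / (R_GAS * T))
        centered = f.rate(T)
        assert centered == pytest.approx(classic, rel=1e-10)

    def test_invariant_linking_kref_and_classic_factor(self):
        f = fit_arrhenius(arrhenius_points(2.221e8, 45760.0))
        assert f.A_classic == pytest.approx(
            f.kref_at_Tref * np.exp(f.Ea / (R_GAS * f.Tref_K)), rel=1e-12
        )

    def test_table_kref_conversion_roundtrip(self):
        """kref at the mean study temperature 0.0453 d⁻¹ with Ea = 70.07 kJ/mol
        converts to a classic pre-exponential factor ≈ 3.41e10 d⁻¹."""
        A = 0.0453 * np.exp(70070.0 / (R_GAS * 308.15))
        assert A == pytest.approx(3.412e10, rel=0.005)
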