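"""Transfer functions, phase/modulation evaluation, cascades, RC mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdfluor import (
    FrequencyResponse,
    LinearFilter,
    MultiExpModel,
    ThreeLevelModel,
    cascade,
    eval_multiexp,
    lifetime_from_rc,
    phase_mod,
    three_level_transfer,
    wrap_phase_deg,
)

HYP = dict(max_examples=30, derandomize=True, deadline=None)


class TestMultiExpTransfer:
    def test_single_component_at_unit_frequency(self):
        m = MultiExpModel([(1.0, 1.0)])
        assert eval_multiexp(m, 1.0) == pytest.approx(0.5 - 0.5j)

    def test_dc_value_is_sum_of_fractions(self, fig5_mixture):
        assert eval_multiexp(fig5_mixture, 0.0) == pytest.approx(1.0 + 0.0j)

    def test_mixture_phase_masked_peak_and_turnover(self, fig5_mixture):
        # the slow component's phase is masked by the fast one: a local
        # peak well below 90 degrees, then a turnover dip before the fast
        # component's own knee takes the phase up again
        omega = np.logspace(-2, 6, 10_000)
        phase, _ = phase_mod(fig5_mixture, omega)
        assert np.max(phase) < 90.0
        slow_band = omega < 100.0
        ipk = int(np.argmax(phase[slow_band]))
        assert 0 < ipk < slow_band.sum() - 1  # interior local maximum
        peak = phase[slow_band][ipk]
        trough = phase[(omega > omega[slow_band][ipk]) & (omega < 1e3)].min()
        assert trough < peak - 10.0  # pronounced turnover

    @given(
        omega=st.floats(1e-6, 1e6),
        tau=st.floats(1e-6, 1e3),
        f=st.floats(0.01, 10.0),
    )
    @settings(**HYP)
    def test_negative_frequency_gives_conjugate(self, omega, tau, f):
        m = MultiExpModel([(f, tau), (0.5 * f, 3.7 * tau)])
        assert eval_multiexp(m, -omega) == pytest.approx(np.conj(eval_multiexp(m, omega)))

    def test_omega_must_be_finite(self):
        with pytest.raises(ValueError):
            eval_multiexp(MultiExpModel([(1.0, 1.0)]), np.inf)


class TestPhaseMod:
    def test_unit_lifetime_at_unit_frequency(self):
        phase, mod = phase_mod(MultiExpModel([(1.0, 1.0)]), 1.0)
        assert phase == pytest.approx(45.0)
        assert mod == pytest.approx(1.0 / math.sqrt(2.0))

    def test_dc_is_zero_phase_unit_mod(self, fig5_mixture):
        phase, mod = phase_mod(fig5_mixture, 0.0)
        assert phase == pytest.approx(0.0)
        assert mod == pytest.approx(1.0)

    def test_tan_phase_equals_omega_tau_on_grid(self):
        tau = 2.5e-4
        omega = np.logspace(0, 6, 200)
        phase, mod = phase_mod(MultiExpModel([(1.0, tau)]), omega)
        np.testing.assert_allclose(np.tan(np.radians(phase)), omega * tau, rtol=1e-10)
        np.testing.assert_allclose(mod, 1.0 / np.sqrt(1.0 + (omega * tau) ** 2), rtol=1e-12)

    def test_single_lifetime_phase_approaches_90_monotonically(self):
        omega = np.logspace(-3, 9, 400)
        phase, _ = phase_mod(MultiExpModel([(1.0, 1.0)]), omega)
        assert np.all(np.diff(phase) > 0)
        assert phase[-1] < 90.0
        assert phase[-1] > 89.99

    @given(tau=st.floats(1e-6, 1e3))
    @settings(**HYP)
    def test_single_lifetime_monotonicity(self, tau):
        omega = np.logspace(math.log10(0.01 / tau), math.log10(100.0 / tau), 300)
        phase, mod = phase_mod(MultiExpModel([(1.0, tau)]), omega)
        assert np.all(np.diff(phase) > 0)
        assert np.all(np.diff(mod) < 0)

    @given(
        f1=st.floats(0.05, 1.0),
        f2=st.floats(0.05, 1.0),
        log_tau2=st.floats(-5, -1),
    )
    @settings(**HYP)
    def test_parallel_sum_phase_stays_in_first_quadrant(self, f1, f2, log_tau2):
        m = MultiExpModel([(f1, 1.0), (f2, 10.0**log_tau2)])
        omega = np.logspace(-3, 8, 500)
        phase, _ = phase_mod(m, omega)
        assert np.all(phase >= 0.0)
        assert np.all(phase < 90.0)

    def test_zero_dc_model_rejected(self):
        class _Fake:
            pass

        zero_gain = LinearFilter(gain=0.0, poles=(-1.0,))
        with pytest.raises(ValueError, match="DC"):
            phase_mod(zero_gain, 1.0)


class TestThreeLevel:
    def test_transfer_structure(self):
        m = ThreeLevelModel(gamma_13=1.0, gamma_21=2.0, gamma_31=0.5, gamma_32=7.0)
        filt = three_level_transfer(m)
        assert filt.gain == 7.0
        assert set(filt.poles) == {-2.0 + 0j, -7.5 + 0j}
        assert filt.zeros == ()

    def test_dc_gain_unity_for_matched_rates(self):
        m = ThreeLevelModel(gamma_13=1.0, gamma_21=1.0, gamma_31=0.0, gamma_32=1.0)
        assert three_level_transfer(m).dc_gain() == pytest.approx(1.0 + 0.0j)

    def test_phase_approaches_180_at_high_frequency(self):
        m = ThreeLevelModel(gamma_13=1.0, gamma_21=1.0, gamma_31=0.0, gamma_32=3.0)
        phase, _ = phase_mod(three_level_transfer(m), 1e8)
        assert phase == pytest.approx(180.0, abs=1e-3)

    def test_fast_relaxation_collapses_to_single_pole(self):
        # the far pole's wing cancels the gain, leaving one low-pass
        m = ThreeLevelModel(gamma_13=1.0, gamma_21=1.0, gamma_31=0.0, gamma_32=1e6)
        filt = three_level_transfer(m)
        omega = np.logspace(-2, 2, 200)
        phase, _ = phase_mod(filt, omega)
        single, _ = phase_mod(MultiExpModel([(1.0, 1.0)]), omega)
        assert np.max(np.abs(phase - single)) < 0.1

    def test_very_fast_relaxation_45_degrees_at_corner(self):
        m = ThreeLevelModel(gamma_13=1.0, gamma_21=1.0, gamma_31=0.0, gamma_32=1e11)
        phase, _ = phase_mod(three_level_transfer(m), 1.0)
        assert phase == pytest.approx(45.0, abs=1e-6)

    def test_missing_emission_path_rejected(self):
        with pytest.raises(ValueError):
            ThreeLevelModel(gamma_13=1.0, gamma_21=0.0, gamma_31=0.0, gamma_32=1.0)
        with pytest.raises(ValueError):
            ThreeLevelModel(gamma_13=1.0, gamma_21=1.0, gamma_31=0.0, gamma_32=0.0)


class TestCascade:
    def test_single_filter_identity(self):
        f = LinearFilter(gain=2.0, poles=(-1.0,), zeros=(-3.0,))
        c = cascade([f])
        assert c.gain == f.gain and c.poles == f.poles and c.zeros == f.zeros

    def test_two_identical_low_passes_double_the_phase(self):
        f = LinearFilter(gain=1.0, poles=(-1.0,))
        phase, _ = phase_mod(cascade([f, f]), 1.0)
        assert phase == pytest.approx(90.0)

    def test_fluorophore_plus_detector_is_sum_of_arctans(self):
        tau, gamma_d = 1e-3, 5e3
        fluor = LinearFilter(gain=1.0 / tau, poles=(-1.0 / tau,))
        det = LinearFilter(gain=gamma_d, poles=(-gamma_d,))
        omega = np.logspace(0, 5, 50)
        phase, _ = phase_mod(cascade([fluor, det]), omega)
        expected = np.degrees(np.arctan(omega * tau) + np.arctan(omega / gamma_d))
        np.testing.assert_allclose(phase, expected, atol=1e-9)

    @given(
        p1=st.floats(1e-3, 1e3),
        p2=st.floats(1e-3, 1e3),
        omega=st.floats(1e-3, 1e3),
    )
    @settings(**HYP)
    def test_phase_additivity(self, p1, p2, omega):
        f1 = LinearFilter(gain=1.0, poles=(-p1,))
        f2 = LinearFilter(gain=1.0, poles=(-p2,))
        ph1, _ = phase_mod(f1, omega)
        ph2, _ = phase_mod(f2, omega)
        ph12, _ = phase_mod(cascade([f1, f2]), omega)
        assert abs(ph12 - (ph1 + ph2)) % 360.0 < 1e-9

    def test_n_stage_phase_bounded_by_90n(self):
        filters = [LinearFilter(gain=1.0, poles=(-g,)) for g in (0.1, 1.0, 10.0)]
        phase, _ = phase_mod(cascade(filters), np.logspace(-3, 6, 300))
        assert np.all(phase < 270.0)

    def test_empty_cascade_rejected(self):
        with pytest.raises(ValueError):
            cascade([])


class TestLifetimeFromRC:
    @pytest.mark.parametrize(
        "r, c, expected, tol",
        [
            (159e3, 1e-6, 0.99903, 1e-4),
            (1.6e3, 100e-9, 1.005e-3, 1e-6),
            (1.0 / (2.0 * math.pi), 1.0, 1.0, 1e-15),
        ],
    )
    def test_two_pi_rc(self, r, c, expected, tol):
        assert lifetime_from_rc(r, c) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("r, c", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_inputs_rejected(self, r, c):
        with pytest.raises(ValueError):
            lifetime_from_rc(r, c)


class TestValidation:
    def test_model_invariants(self):
        with pytest.raises(ValueError):
            MultiExpModel([])
        with pytest.raises(ValueError):
            MultiExpModel([(1.0, -1.0)])
        with pytest.raises(ValueError):
            MultiExpModel([(-0.1, 1.0)])
        with pytest.raises(ValueError):
            MultiExpModel([(0.0, 1.0), (0.0, 2.0)])
        with pytest.raises(ValueError, match="coincide"):
            MultiExpModel([(0.5, 1.0), (0.5, 1.0 + 1e-12)])

    def test_unstable_filter_rejected(self):
        with pytest.raises(ValueError):
            LinearFilter(gain=1.0, poles=(1.0,))

    def test_frequency_response_invariants(self):
        with pytest.raises(ValueError):
            FrequencyResponse(np.array([2.0, 1.0]), np.zeros(2), np.ones(2))
        with pytest.raises(ValueError):
            FrequencyResponse(np.array([1.0, 2.0]), np.zeros(2), np.array([0.5, 1.5]))

    def test_frequency_response_csv_roundtrip(self, tmp_path):
        fr = FrequencyResponse(
            np.array([1.0, 10.0]),
            np.array([5.0, 45.0]),
            np.array([0.99, 0.7]),
            phase_sd=np.array([0.1, 0.2]),
        )
        path = tmp_path / "curve.csv"
        fr.to_csv(path)
        back = FrequencyResponse.from_csv(path)
        np.testing.assert_allclose(back.frequencies, fr.frequencies)
        np.testing.assert_allclose(back.phase_deg, fr.phase_deg)
        np.testing.assert_allclose(back.phase_sd, fr.phase_sd)
        assert back.mod_sd is None


@pytest.mark.parametrize(
    "phase, mode, expected",
    [(190.0, "principal", -170.0), (-180.0, "principal", 180.0), (100.0, "arctan", -80.0), (54.0, "arctan", 54.0)],
)
def test_phase_wrapping(phase, mode, expected):
    assert wrap_phase_deg(phase, mode) == pytest.approx(expected)
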