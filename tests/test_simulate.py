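"""Synthetic-batch generator: kinetic shapes, bilinear structure, faults."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rennetmon as rm


def n_local_maxima(x: np.ndarray) -> int:
    """Count strict local maxima of a sequence (plateaus merged)."""
    # collapse exact plateaus so (1, 2, 2, 1) counts one peak
    keep = np.concatenate([[True], np.diff(x) != 0])
    y = x[keep]
    if y.size < 3:
        return 1
    interior = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
    ends = int(y[0] > y[1]) + int(y[-1] > y[-2])
    return int(interior.sum()) + ends


class TestConcentrationProfiles:
    def test_pulse_peaks_at_transition_time(self, times30):
        kin = rm.KineticParams(transition_time=7.0)
        C = rm.make_concentration_profiles(kin, times30)
        assert times30[np.argmax(C[:, 1])] == 7.0

    def test_offgrid_transition_peaks_at_nearest_point(self, times30):
        kin = rm.KineticParams(transition_time=7.4)
        C = rm.make_concentration_profiles(kin, times30)
        assert times30[np.argmax(C[:, 1])] == 7.0

    @given(
        tt=st.floats(3.0, 25.0),
        steep=st.floats(0.3, 3.0),
        amp=st.floats(0.05, 1.0),
        width=st.floats(0.5, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_columns_unimodal_bounded(self, tt, steep, amp, width):
        kin = rm.KineticParams(
            transition_time=tt,
            steepness=steep,
            transition_amplitude=amp,
            pulse_width=width,
        )
        C = rm.make_concentration_profiles(kin, rm.default_times())
        assert C.min() >= 0.0 and C.max() <= 1.0
        for j in range(3):
            assert n_local_maxima(C[:, j]) == 1

    def test_slow_batch_gel_rise_lags_fast_batch(self, times30):
        slow = rm.make_concentration_profiles(
            rm.KineticParams(transition_time=14.5), times30
        )
        fast = rm.make_concentration_profiles(
            rm.KineticParams(transition_time=6.0), times30
        )

        def half_rise(col):
            return times30[np.argmax(col >= 0.5 * col.max())]

        assert half_rise(slow[:, 2]) > half_rise(fast[:, 2])

    def test_rejects_bad_time_grid(self, center_kinetics):
        with pytest.raises(ValueError):
            rm.make_concentration_profiles(
                center_kinetics, np.array([1.0, 2.0, 2.0, 3.0, 4.0])
            )
        with pytest.raises(ValueError):
            rm.KineticParams(transition_time=7.0, steepness=-1.0)


class TestSpectralProfiles:
    def test_rank_three_and_nonnegative(self, small_grid):
        S = rm.make_spectral_profiles(small_grid, seed=0)
        assert S.min() >= 0.0
        sv = np.linalg.svd(S, compute_uv=False)
        assert sv[2] > 1e-6 * sv[0]

    def test_same_seed_bit_identical(self, small_grid):
        a = rm.make_spectral_profiles(small_grid, seed=7)
        b = rm.make_spectral_profiles(small_grid, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_rejects_grid_not_covering_window(self):
        with pytest.raises(ValueError):
            rm.make_spectral_profiles(np.linspace(9000, 6000, 100), seed=0)


class TestSimulateBatch:
    def test_zero_noise_equals_product(self, noiseless_truth, noiseless_batch):
        expect = noiseless_truth.C_true @ noiseless_truth.S_true
        np.testing.assert_array_equal(noiseless_batch.absorbance, expect)

    def test_noiseless_numerical_rank_three(self, noiseless_batch):
        sv = np.linalg.svd(noiseless_batch.absorbance, compute_uv=False)
        assert sv[3] <= 1e-10 * sv[0]

    def test_injected_noise_sd_recovered(self, center_kinetics):
        truth = rm.make_ground_truth(center_kinetics, noise_sd=1e-3)
        batch = rm.simulate_batch(truth, seed=4)
        resid = batch.absorbance - truth.C_true @ truth.S_true
        assert abs(resid.std(ddof=1) - 1e-3) < 1e-4  # 51,900 draws

    def test_seed_contract(self, noiseless_truth, center_kinetics):
        same1 = rm.simulate_batch(noiseless_truth, seed=2)
        same2 = rm.simulate_batch(noiseless_truth, seed=2)
        np.testing.assert_array_equal(same1.absorbance, same2.absorbance)
        noisy = rm.make_ground_truth(center_kinetics, noise_sd=0.003)
        a = rm.simulate_batch(noisy, seed=1)
        b = rm.simulate_batch(noisy, seed=2)
        assert not np.array_equal(a.absorbance, b.absorbance)

    def test_dimension_mismatch_rejected(self, noiseless_truth):
        import dataclasses

        bad = dataclasses.replace(
            noiseless_truth, C_true=noiseless_truth.C_true[:, :2]
        )
        with pytest.raises(ValueError, match="mismatch"):
            rm.simulate_batch(bad, seed=0)


class TestFaults:
    def test_half_rennet_delays_transition(self):
        kin = rm.KineticParams(transition_time=7.0)
        out = rm.apply_fault(kin, rm.FaultSpec(kind="half_rennet", severity=0.5))
        assert out.transition_time > 9.0
        assert out.transition_amplitude < kin.transition_amplitude

    def test_zero_severity_is_identity(self):
        kin = rm.KineticParams(transition_time=7.0)
        for kind in rm.FAULT_KINDS:
            out = rm.apply_fault(kin, rm.FaultSpec(kind=kind, severity=0.0))
            assert out == kin

    @pytest.mark.parametrize("kind", rm.FAULT_KINDS)
    def test_peak_shift_at_half_severity(self, kind, times30):
        kin = rm.KineticParams(transition_time=7.0)
        faulted = rm.apply_fault(kin, rm.FaultSpec(kind=kind, severity=0.5))
        t_ok = times30[np.argmax(rm.make_concentration_profiles(kin, times30)[:, 1])]
        t_bad = times30[
            np.argmax(rm.make_concentration_profiles(faulted, times30)[:, 1])
        ]
        assert abs(t_bad - t_ok) >= 2.0

    def test_fault_kinds_produce_distinct_profiles(self, times30):
        kin = rm.KineticParams(transition_time=7.0)
        a = rm.apply_fault(kin, rm.FaultSpec(kind="heating_off", severity=0.5))
        b = rm.apply_fault(kin, rm.FaultSpec(kind="half_rennet", severity=0.5))
        Ca = rm.make_concentration_profiles(a, times30)
        Cb = rm.make_concentration_profiles(b, times30)
        assert np.abs(Ca[:, 1] - Cb[:, 1]).max() > 0.05

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown fault kind"):
            rm.FaultSpec(kind="power_surge")


class TestRheology:
    def test_logistic_midpoint_and_asymptote(self, times30):
        curve = rm.simulate_rheology(100.0, 10.0, 2.0, times30)
        assert curve.G_prime[np.where(times30 == 10.0)[0][0]] == pytest.approx(50.0)
        far = rm.simulate_rheology(100.0, 10.0, 2.0, np.array([1.0, 500.0]))
        assert far.G_prime[-1] == pytest.approx(100.0, abs=1e-6)

    def test_point_value_matches_formula(self):
        curve = rm.simulate_rheology(100.0, 10.0, 2.0, np.array([1.0, 12.0]))
        assert curve.G_prime[-1] == pytest.approx(100.0 / (1 + np.exp(-1.0)))

    def test_noiseless_curve_monotone(self, times30):
        curve = rm.simulate_rheology(80.0, 12.0, 1.5, times30)
        assert np.all(np.diff(curve.G_prime) > 0)

    def test_zero_scale_rejected(self, times30):
        with pytest.raises(ValueError):
            rm.simulate_rheology(100.0, 10.0, 0.0, times30)
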