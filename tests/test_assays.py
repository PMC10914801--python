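"""Assay formulas: SEC calibration, ATPase slope, kymographs and periods,
phenotype thresholds, QCMD frequency drop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minescreen.assays import (
    CellPopulation, NoOscillationError, atpase_rate, build_kymograph,
    classify_phenotype, estimate_oligomer_mass, fit_sec_calibration, kav,
    oscillation_period, qcmd_frequency_drop, wave_occurrence,
    SEC_STANDARD_MASSES,
)
from minescreen.synthetic import (
    synth_cell_lengths, synth_kymograph, synth_sec_standards,
)


class TestKav:
    def test_void_volume_limit(self):
        assert kav(8.0, 8.0, 23.5) == 0.0

    def test_total_volume_limit(self):
        assert kav(23.5, 8.0, 23.5) == 1.0

    def test_midpoint(self):
        assert kav(15.75, 8.0, 23.5) == pytest.approx(0.5)

    @given(st.floats(-50, 50), st.floats(9, 22))
    @settings(deadline=None, max_examples=40)
    def test_affine_invariance(self, shift, ve):
        assert kav(ve + shift, 8.0 + shift, 23.5 + shift) == pytest.approx(
            kav(ve, 8.0, 23.5)
        )

    def test_degenerate_column_rejected(self):
        with pytest.raises(ValueError):
            kav(10.0, 23.5, 23.5)


class TestSecCalibration:
    def test_two_standards_exact_interpolation(self):
        standards = [("a", 100.0, 12.0), ("b", 10.0, 18.0)]
        cal = fit_sec_calibration(standards, vo=8.0)
        for _, mass, ve in standards:
            k = kav(ve, 8.0, 23.5)
            assert cal.slope * np.log10(mass) + cal.intercept == pytest.approx(k)

    def test_noise_free_recovery(self):
        standards = synth_sec_standards(slope=-0.35, intercept=1.1, noise_sd=0.0)
        cal = fit_sec_calibration(standards, vo=8.0)
        assert cal.slope == pytest.approx(-0.35)
        assert cal.intercept == pytest.approx(1.1)

    def test_noisy_slope_within_5_percent(self):
        standards = synth_sec_standards(noise_sd=0.01, seed=21)
        cal = fit_sec_calibration(standards, vo=8.0)
        assert cal.slope == pytest.approx(-0.35, rel=0.05)

    def test_default_standard_masses(self):
        masses = {m for _, m in SEC_STANDARD_MASSES}
        assert masses == {158.0, 75.0, 44.0, 29.0, 13.7, 6.5}

    def test_single_standard_rejected(self):
        with pytest.raises(ValueError):
            fit_sec_calibration([("a", 100.0, 12.0)], vo=8.0)

    def test_negative_slope_on_sane_column(self):
        cal = fit_sec_calibration(synth_sec_standards(), vo=8.0)
        assert cal.slope < 0


class TestOligomerMass:
    def test_standard_inverts_to_its_mass(self):
        standards = synth_sec_standards(noise_sd=0.0)
        cal = fit_sec_calibration(standards, vo=8.0)
        for _, mass, ve in standards:
            assert estimate_oligomer_mass(ve, cal) == pytest.approx(mass, rel=1e-6)

    def test_dimer_mass(self):
        cal = fit_sec_calibration(synth_sec_standards(noise_sd=0.0), vo=8.0)
        monomer = 12.0
        k_dimer = cal.slope * np.log10(2 * monomer) + cal.intercept
        ve = 8.0 + k_dimer * (23.5 - 8.0)
        assert estimate_oligomer_mass(ve, cal) == pytest.approx(2 * monomer,
                                                                rel=1e-6)

    def test_flat_calibration_rejected(self):
        from minescreen.assays import SecCalibration
        cal = SecCalibration(vo=8.0, vc=23.5, slope=0.0, intercept=0.5)
        with pytest.raises(ValueError):
            estimate_oligomer_mass(12.0, cal)


class TestAtpase:
    def test_noiseless_slope(self):
        t = np.linspace(0, 30, 31)
        a = 1.0 - 0.01 * t
        out = atpase_rate(t, a, window=(5, 25))
        assert out["slope_abs_per_min"] == pytest.approx(-0.01)

    def test_noisy_slope_within_10_percent(self):
        rng = np.random.default_rng(23)
        t = np.linspace(0, 30, 61)
        a = 1.0 - 0.02 * t + rng.normal(0, 0.001, t.size)
        out = atpase_rate(t, a, window=(0, 30))
        assert out["slope_abs_per_min"] == pytest.approx(-0.02, rel=0.10)

    def test_flat_trace(self):
        t = np.linspace(0, 10, 11)
        out = atpase_rate(t, np.ones(11), window=(0, 10))
        assert out["slope_abs_per_min"] == pytest.approx(0.0)

    def test_window_outside_trace_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            atpase_rate(t, np.ones(11), window=(20, 30))

    def test_unit_conversion_only_when_supplied(self):
        t = np.linspace(0, 10, 11)
        a = 1.0 - 0.00622 * t
        plain = atpase_rate(t, a, window=(0, 10))
        assert "rate_uM_atp_per_min" not in plain
        converted = atpase_rate(t, a, window=(0, 10),
                                extinction_coeff=6.22, path_length_cm=1.0)
        assert converted["rate_uM_atp_per_min"] == pytest.approx(1.0, rel=1e-6)


class TestKymograph:
    def test_uniform_stack_constant_rows(self):
        stack = np.ones((5, 8, 20))
        kymo, dt = build_kymograph(stack, dt=5.0, n_bins=10)
        assert kymo.shape == (5, 10)
        np.testing.assert_allclose(kymo, 1.0)

    def test_pole_to_pole_oscillation_alternates(self):
        # intensity concentrated at alternating ends of a rod along x
        stack = np.zeros((6, 5, 30)) + 0.1
        for frame in range(6):
            if frame % 2 == 0:
                stack[frame, :, :6] = 1.0
            else:
                stack[frame, :, -6:] = 1.0
        kymo, _ = build_kymograph(stack, dt=5.0, n_bins=10,
                                  mask=np.ones((5, 30), bool))
        left = kymo[:, :3].mean(axis=1)
        right = kymo[:, -3:].mean(axis=1)
        assert ((left > right) == np.array([1, 0, 1, 0, 1, 0], bool)).all()

    def test_row_count_equals_frames(self):
        stack = np.random.default_rng(0).random((7, 6, 12)) + 0.1
        kymo, _ = build_kymograph(stack, dt=2.0)
        assert kymo.shape[0] == 7

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            build_kymograph(np.ones((3, 4, 4)), dt=1.0,
                            mask=np.zeros((4, 4), bool))


class TestOscillationPeriod:
    def test_noiseless_recovery_within_1_percent(self):
        y, dt = synth_kymograph(period_s=42.0, dt=5.0, n_frames=60,
                                noise_sd=0.0)
        assert oscillation_period(y, dt)["period_s"] == pytest.approx(42.0,
                                                                      rel=0.01)

    @pytest.mark.parametrize("period", [30.0, 42.0, 120.0, 174.0])
    def test_noisy_recovery_within_2_percent(self, period):
        y, dt = synth_kymograph(period_s=period, dt=5.0, n_frames=120,
                                amplitude=1.0, noise_sd=0.1, seed=29)
        assert oscillation_period(y, dt)["period_s"] == pytest.approx(
            period, rel=0.02
        )

    def test_constant_signal_flagged(self):
        with pytest.raises(NoOscillationError):
            oscillation_period(np.ones(50), dt=5.0)

    def test_pure_noise_flagged(self):
        rng = np.random.default_rng(31)
        with pytest.raises(NoOscillationError):
            oscillation_period(rng.normal(0, 1, 200), dt=5.0)


class TestPhenotype:
    def test_high_minicell_population(self):
        lengths = synth_cell_lengths(n=2000, minicell_frac=0.29, seed=1)
        assert classify_phenotype(CellPopulation(lengths)) == "minicell"

    def test_wildtype_like_population_is_normal(self):
        pop = CellPopulation(np.concatenate([
            np.full(979, 4.0), np.full(21, 0.5)      # 2.1% minicells
        ]))
        assert pop.minicell_fraction == pytest.approx(0.021)
        assert classify_phenotype(pop) == "normal"

    def test_boundary_exactly_6_3_percent_is_normal(self):
        pop = CellPopulation(np.concatenate([
            np.full(937, 4.0), np.full(63, 0.5)      # exactly 6.3%
        ]))
        assert pop.minicell_fraction == pytest.approx(0.063)
        assert classify_phenotype(pop) == "normal"

    def test_filamentous_takes_precedence(self):
        lengths = np.concatenate([np.full(50, 0.5), np.full(50, 30.0)])
        assert classify_phenotype(CellPopulation(lengths)) == "filamentous"

    def test_derived_statistics(self):
        pop = CellPopulation(np.array([2.0, 3.0, 4.0]))
        assert pop.median_length == 3.0


class TestWaveOccurrenceAndQcmd:
    @pytest.mark.parametrize("n_osc,n_total,expect", [
        (0, 10, 0.0), (10, 10, 1.0), (7, 20, 0.35),
    ])
    def test_wave_occurrence(self, n_osc, n_total, expect):
        assert wave_occurrence(n_osc, n_total) == pytest.approx(expect)

    def test_wave_occurrence_preconditions(self):
        with pytest.raises(ValueError):
            wave_occurrence(5, 0)
        with pytest.raises(ValueError):
            wave_occurrence(11, 10)

    def test_constant_trace_no_drop(self):
        assert qcmd_frequency_drop(np.full(20, -3.0)) == 0.0

    def test_step_drop_recovered(self):
        trace = np.concatenate([np.zeros(20), np.full(20, -30.0)])
        assert qcmd_frequency_drop(trace) == pytest.approx(-30.0)

    def test_smoothed_extrema_by_hand(self):
        trace = np.array([0.0, 0, 0, 0, 0, -10, -10, -10, -10, -10])
        # smoothed: first window mean 0, last window mean -10
        assert qcmd_frequency_drop(trace) == pytest.approx(-10.0)

    def test_noise_drop_bounded_by_smoothed_range(self):
        rng = np.random.default_rng(37)
        trace = rng.normal(0, 1, 200)
        smoothed = np.convolve(trace, np.ones(5) / 5, mode="valid")
        drop = qcmd_frequency_drop(trace)
        assert drop == pytest.approx(smoothed.min() - smoothed.max())
        assert abs(drop) <= np.ptp(trace)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            qcmd_frequency_drop(np.array([1.0, 2.0, 3.0]))
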