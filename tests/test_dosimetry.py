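"""Decay correction, time-activity integration and the absorbed-dose model."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from cedose.dosimetry import (
    DecayModel,
    TimeActivityCurve,
    absorbed_dose,
    build_tac,
    cumulated_activity,
    decay_correct,
    dose_summary,
    organ_dose_local,
    organ_geometric_mean,
    percent_injected_dose,
    urine_excretion,
)
from cedose.synthetic import make_phantom, simulate_imaging_series, simulate_urine_samples

MODEL = DecayModel()


class TestDecay:
    def test_lambda_is_ln2_over_half_life(self):
        assert MODEL.lambda_per_h == pytest.approx(math.log(2) / 89.2, rel=1e-15)

    def test_one_half_life_back_doubles(self):
        assert decay_correct(1.0, 89.2, 0.0) == pytest.approx(2.0, rel=1e-12)

    def test_same_time_identity(self):
        assert decay_correct(3.7, 24.0, 24.0) == 3.7

    def test_forward_192h_factor(self):
        assert decay_correct(1.0, 0.0, 192.0) == pytest.approx(0.2249277602174928, rel=1e-12)

    def test_round_trip_identity(self):
        x = decay_correct(decay_correct(5.0, 0.0, 120.0), 120.0, 0.0)
        assert x == pytest.approx(5.0, abs=1e-12)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValueError):
            DecayModel(half_life_h=0.0)


class TestBuildTac:
    def _frames(self, tumor_fraction, totals=(10.0, 5.0)):
        """Two-frame series where the tumor region holds a known count share."""
        from cedose.quant import ActivityVolume, StandardSource

        frames = []
        for t, total in zip((0.0, 24.0), totals):
            counts = np.zeros((2, 1, 1))
            counts[0, 0, 0] = tumor_fraction * 100.0
            counts[1, 0, 0] = (1 - tumor_fraction) * 100.0
            frames.append(
                ActivityVolume(counts, (1, 1, 1), t, StandardSource(total, 100.0))
            )
        return frames

    def test_tumor_equals_brain(self):
        mask = np.array([[[True]], [[True]]])
        tac = build_tac(self._frames(0.3), mask)
        np.testing.assert_allclose(tac.activities_mCi, [10.0, 5.0])

    def test_half_fraction_half_activity(self):
        mask = np.array([[[True]], [[False]]])
        tac = build_tac(self._frames(0.5), mask)
        assert tac.activities_mCi[0] == pytest.approx(5.0)

    def test_requires_eoi_frame(self):
        frames = self._frames(0.5)
        frames[0].time_h = 12.0
        with pytest.raises(ValueError, match="EOI"):
            build_tac(frames, np.array([[[True]], [[False]]]))

    def test_zero_brain_counts_rejected(self):
        from cedose.quant import ActivityVolume, StandardSource

        frames = [
            ActivityVolume(np.zeros((1, 1, 1)), (1, 1, 1), t, StandardSource(1.0, 1.0))
            for t in (0.0, 24.0)
        ]
        with pytest.raises(ValueError, match="counts are 0"):
            build_tac(frames, np.ones((1, 1, 1), bool))

    def test_noiseless_phantom_tac_matches_decayed_truth(self, sphere_spec):
        gtv, activity = make_phantom(sphere_spec, total_activity_mCi=4.0)
        times = [0.0, 24.0, 120.0, 192.0]
        frames = simulate_imaging_series(
            activity, sphere_spec.voxel_size_mm, times_h=times, noise=False
        )
        tac = build_tac(frames, gtv)
        truth = activity[gtv].sum() * np.array([MODEL.decay_factor(t) for t in times])
        np.testing.assert_allclose(tac.activities_mCi, truth, rtol=1e-6)


class TestCumulatedActivity:
    def test_constant_curve_rectangle(self):
        tac = TimeActivityCurve(np.arange(0.0, 11.0), np.full(11, 2.0))
        assert cumulated_activity(tac, end_h=10.0) == pytest.approx(20.0)

    def test_exponential_matches_closed_form(self):
        t = np.arange(0.0, 193.0)
        a0 = 3.0
        tac = TimeActivityCurve(t, a0 * 2 ** (-t / 89.2))
        closed = a0 * (1 - 2 ** (-192 / 89.2)) / MODEL.lambda_per_h
        assert cumulated_activity(tac, end_h=192.0) == pytest.approx(closed, rel=5e-3)

    @pytest.mark.parametrize(
        "fn",
        [lambda t: 2.0 * np.exp(-0.01 * t), lambda t: 1.0 + 0.5 * t + 0.001 * t**2],
        ids=["exponential", "polynomial"],
    )
    def test_trapezoid_vs_quadrature_oracle(self, fn):
        """1 h sampling agrees with adaptive quadrature to < 1e-3 relative."""
        t = np.arange(0.0, 193.0)
        tac = TimeActivityCurve(t, fn(t))
        oracle, _ = quad(fn, 0.0, 192.0)
        assert cumulated_activity(tac, end_h=192.0) == pytest.approx(oracle, rel=1e-3)

    def test_physical_decay_tail_recovers_total_decays(self):
        t = np.arange(0.0, 192.5, 0.5)
        a0 = 1.7
        tac = TimeActivityCurve(t, a0 * 2 ** (-t / 89.2))
        total = cumulated_activity(tac, end_h=192.0, tail="physical_decay")
        assert total == pytest.approx(a0 / MODEL.lambda_per_h, rel=5e-3)

    def test_window_beyond_samples_rejected_without_tail(self):
        tac = TimeActivityCurve([0.0, 24.0], [1.0, 0.8])
        with pytest.raises(ValueError, match="extends past"):
            cumulated_activity(tac, end_h=192.0, tail="none")

    def test_interpolates_interior_window_edge(self):
        tac = TimeActivityCurve([0.0, 100.0], [1.0, 1.0])
        assert cumulated_activity(tac, end_h=50.0) == pytest.approx(50.0)


class TestAbsorbedDose:
    def test_unit_case_gives_dose_constant(self):
        assert absorbed_dose(1.0, 1.0) == 7.126

    def test_linear_in_cumulated_activity(self):
        assert absorbed_dose(100.0, 10.0) == pytest.approx(71.26)

    def test_inverse_in_mass(self):
        assert absorbed_dose(5.0, 2.0) == pytest.approx(absorbed_dose(5.0, 1.0) / 2.0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            absorbed_dose(1.0, 0.0)

    def test_dichotomy_flag(self):
        assert dose_summary(100.0, 7.0).ge_100Gy  # 101.8 Gy
        assert not dose_summary(10.0, 7.0).ge_100Gy

    def test_end_to_end_noiseless_patient_matches_closed_form(self, sphere_spec):
        """Phantom -> imaging -> TAC -> cumulated activity -> dose agrees with
        the analytic pure-decay integral to < 1%."""
        gtv, activity = make_phantom(sphere_spec, total_activity_mCi=8.0)
        times = np.arange(0.0, 193.0, 1.0)
        frames = simulate_imaging_series(
            activity, sphere_spec.voxel_size_mm, times_h=times, noise=False
        )
        tac = build_tac(frames, gtv)
        a_cum = cumulated_activity(tac, end_h=192.0)
        mass_g = gtv.sum() * np.prod(sphere_spec.voxel_size_mm) / 1000.0
        dose = absorbed_dose(a_cum, mass_g)
        a0 = activity[gtv].sum()
        closed = a0 * (1 - 2 ** (-192 / 89.2)) / MODEL.lambda_per_h * 7.126 / mass_g
        assert dose == pytest.approx(closed, rel=0.01)


class TestPlanarAndExcretion:
    def test_geometric_mean_cases(self):
        assert organ_geometric_mean(4.0, 9.0) == pytest.approx(6.0)
        assert organ_geometric_mean(7.0, 7.0) == pytest.approx(7.0)
        assert organ_geometric_mean(0.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            organ_geometric_mean(-1.0, 5.0)

    def test_percent_injected_dose(self):
        assert percent_injected_dose(22.3, 22.3) == pytest.approx(100.0)
        assert percent_injected_dose(2.23, 22.3) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            percent_injected_dose(1.0, 0.0)

    def test_disjoint_compartments_conserve_activity(self):
        parts = [5.0, 7.0, 10.0]  # mCi, summing below administered 22.3
        assert sum(percent_injected_dose(p, 22.3) for p in parts) <= 100.0 + 1e-9

    def test_organ_dose_local_unit_conversion(self):
        dose_cGy, norm = organ_dose_local(1.0, 100.0, 2.0)
        assert dose_cGy == pytest.approx(7.126)
        assert norm == pytest.approx(3.563)

    def test_organ_dose_normalized_identity_at_1mCi(self):
        dose_cGy, norm = organ_dose_local(3.0, 50.0, 1.0)
        assert norm == dose_cGy

    def test_organ_dose_monotone_in_cumulated(self):
        d1, _ = organ_dose_local(1.0, 100.0, 1.0)
        d2, _ = organ_dose_local(2.0, 100.0, 1.0)
        assert d2 > d1

    def test_urine_zero_counts(self):
        rows = urine_excretion([(0.0, 24.0, 0.0, 1e5)], administered_mCi=10.0)
        assert rows[0]["pct_id"] == 0.0

    def test_urine_round_trip_ten_percent_leak(self):
        samples = simulate_urine_samples(22.3, leak_fractions=[(0.0, 24.0, 0.10)])
        rows = urine_excretion(samples, administered_mCi=22.3)
        assert rows[0]["pct_id"] == pytest.approx(10.0, rel=1e-9)

    def test_urine_cumulative_nondecreasing_and_overlap_rejected(self):
        samples = simulate_urine_samples(
            10.0, leak_fractions=[(0.0, 24.0, 0.10), (24.0, 48.0, 0.02)]
        )
        rows = urine_excretion(samples, administered_mCi=10.0)
        cum = [r["cumulative_pct_id"] for r in rows]
        assert cum == sorted(cum)
        with pytest.raises(ValueError, match="overlap"):
            urine_excretion(
                [(0.0, 24.0, 1.0, 1e5), (12.0, 36.0, 1.0, 1e5)], administered_mCi=10.0
            )
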