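"""Circular smoothing, peak detection and population peak statistics."""

import numpy as np
import pytest

from rnflasym import (
    AngularField,
    CohortParams,
    DEG_PER_SAMPLE,
    N_LOCATIONS,
    PeakSet,
    circular_moving_average,
    detect_peaks,
    generate_population,
    location_angles,
    mirror_profile,
    population_peak_stats,
    smoothing_window_size,
)

from conftest import make_pair


class TestSmoothing:
    def test_window_spans_51_samples_at_12deg(self):
        assert smoothing_window_size(12.0) == 51

    def test_constant_profile_unchanged(self):
        x = np.full(N_LOCATIONS, 42.0)
        assert np.allclose(circular_moving_average(x), 42.0)

    def test_impulse_response(self):
        x = np.zeros(N_LOCATIONS)
        x[0] = 1.0
        out = circular_moving_average(x, 12.0)
        inside = (np.arange(N_LOCATIONS) <= 25) | (np.arange(N_LOCATIONS) >= 768 - 25)
        assert np.allclose(out[inside], 1.0 / 51.0)
        assert np.all(out[~inside] == 0.0)

    def test_circular_mean_preserved(self):
        rng = np.random.default_rng(2)
        x = rng.normal(100, 10, N_LOCATIONS)
        assert circular_moving_average(x).mean() == pytest.approx(x.mean())

    def test_never_increases_maximum(self):
        rng = np.random.default_rng(3)
        x = rng.normal(100, 10, N_LOCATIONS)
        assert circular_moving_average(x).max() <= x.max() + 1e-12

    @pytest.mark.parametrize("hw", [0.0, -3.0, 180.0, 200.0])
    def test_invalid_halfwidth(self, hw):
        with pytest.raises(ValueError):
            circular_moving_average(np.ones(N_LOCATIONS), hw)

    def test_missing_values_rejected(self):
        x = np.ones(N_LOCATIONS)
        x[5] = np.nan
        with pytest.raises(ValueError, match="missing"):
            circular_moving_average(x)


def two_bump_profile(sup=70.0, inf=290.0, width=26.0):
    f = AngularField(60.0, ((sup, width, 75.0), (inf, width, 80.0)))
    return f(location_angles())


class TestDetectPeaks:
    def test_two_bump_centers_recovered(self):
        smoothed = circular_moving_average(two_bump_profile(70.0, 290.0))
        ps = detect_peaks(smoothed)
        assert abs(ps.sup_peak - 70.0) <= DEG_PER_SAMPLE
        assert abs(ps.inf_peak - 290.0) <= DEG_PER_SAMPLE
        assert not ps.degenerate

    def test_interpeak_angle_through_temporal_pole(self):
        ps = PeakSet(sup_peak=60.0, inf_peak=300.0)
        assert ps.interpeak_angle == pytest.approx(120.0)

    def test_mirrored_profile_swaps_peaks(self):
        x = circular_moving_average(two_bump_profile(65.0, 280.0))
        ps = detect_peaks(x)
        ps_m = detect_peaks(mirror_profile(x))
        assert ps_m.sup_peak == pytest.approx(360.0 - ps.inf_peak)
        assert ps_m.inf_peak == pytest.approx(360.0 - ps.sup_peak)

    def test_rotation_recovers_centers_to_grid_resolution(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            rot = float(rng.uniform(-20.0, 20.0))
            smoothed = circular_moving_average(two_bump_profile(70.0 + rot, 290.0 + rot))
            ps = detect_peaks(smoothed)
            assert abs(ps.sup_peak - (70.0 + rot)) <= DEG_PER_SAMPLE
            assert abs(ps.inf_peak - (290.0 + rot)) <= DEG_PER_SAMPLE

    def test_flat_half_flagged_degenerate(self):
        x = np.zeros(N_LOCATIONS)
        x[500] = 5.0  # inferior peak only; superior half flat
        assert detect_peaks(x).degenerate

    def test_ties_break_toward_smaller_angle(self):
        x = np.zeros(N_LOCATIONS)
        x[100] = x[200] = 3.0
        x[500] = 1.0
        assert detect_peaks(x).sup_peak == pytest.approx(100 * DEG_PER_SAMPLE)


class TestPopulationStats:
    def test_null_shifts_not_significant(self):
        params = CohortParams(n_subjects=40, seed=21, noise_sd=1.0,
                              asym_sd_field=AngularField(0.5))
        stats = population_peak_stats(generate_population(params))
        assert abs(stats.sup_shift_mean) < 1.0
        assert abs(stats.inf_shift_mean) < 1.0
        assert stats.sup_shift_p > 0.05 and stats.inf_shift_p > 0.05
        assert stats.n_used == 40

    def test_configured_inferior_shift_recovered(self):
        params = CohortParams(
            n_subjects=60, seed=22, peak_shift_inf_deg=4.42, noise_sd=1.0,
            asym_sd_field=AngularField(0.5),
        )
        stats = population_peak_stats(generate_population(params))
        se = 3.0 * DEG_PER_SAMPLE  # grid quantization dominates the noise here
        assert stats.inf_shift_mean == pytest.approx(4.42, abs=3 * se)
        assert stats.inf_shift_p < 0.05
        # interpeak angle shrinks in OS when its inferior peak moves temporally
        assert stats.interpeak_diff_mean < 0

    def test_exact_linear_relation_gives_unit_r2(self):
        """Inferior-bump shifts proportional to rd on exact grid multiples:
        interpeak difference = -0.1 * rd, so r = -1 and R^2 = 1."""
        pairs = []
        base = two_bump_profile(70.0, 290.0)
        for k in range(-6, 6):
            rd = 4.6875 * k  # shift 0.1*rd is then a whole number of samples
            shift_deg = 0.1 * rd
            os_norm = AngularField(
                60.0, ((70.0, 26.0, 75.0), (290.0 + shift_deg, 26.0, 80.0))
            )(location_angles())
            pairs.append(make_pair(base, os_norm, subject_id=f"S{k}", rd=rd))
        stats = population_peak_stats(pairs)
        assert stats.pearson_r == pytest.approx(-1.0, abs=1e-9)
        assert stats.variance_explained_by_rd == pytest.approx(1.0, abs=1e-9)

    def test_requires_ten_subjects(self):
        params = CohortParams(n_subjects=5, seed=1)
        with pytest.raises(ValueError):
            population_peak_stats(generate_population(params))
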