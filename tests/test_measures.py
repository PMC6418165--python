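"""Coarticulation score, peak structure, and the spatial measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString, Point

from coartkin.errors import MeasureUndefinedError
from coartkin.layout import default_layout
from coartkin.measures import (
    PeakStructure,
    analyze_trial,
    coarticulation_score,
    count_velocity_peaks,
    find_peak_structure,
    normalize_duration,
    normalize_score,
    path_offset_xy,
    spatial_error_xy,
)
from coartkin.preprocess import VelocityProfile

from conftest import DT
from test_preprocess import multi_bell_profile


def structure(peaks, troughs):
    """PeakStructure from plain height lists (indices are dummies)."""
    return PeakStructure(
        peaks=[(10 * (i + 1), h) for i, h in enumerate(peaks)],
        troughs={k + 1: (15 + 10 * k, h) for k, h in enumerate(troughs)},
    )


class TestScoreFormula:
    def test_fully_stopped_scores_zero(self):
        assert coarticulation_score(structure([40, 38, 42, 36], [0, 0, 0])) == 0.0

    def test_flat_plateau_scores_hundred(self):
        assert coarticulation_score(structure([30, 30, 30, 30], [30, 30, 30])) == 100.0

    def test_hand_arithmetic(self):
        # 100 * mean(8, 7.6) / mean(40, 38, 42, 36) = 100 * 7.8 / 39
        ps = structure([40, 38, 42, 36], [8.0, 0.0, 7.6])
        assert coarticulation_score(ps) == pytest.approx(20.0)

    def test_second_trough_is_ignored(self):
        a = structure([40, 38, 42, 36], [8.0, 0.0, 7.6])
        b = structure([40, 38, 42, 36], [8.0, 33.0, 7.6])
        assert coarticulation_score(a) == coarticulation_score(b)

    def test_zero_peaks_undefined(self):
        with pytest.raises(MeasureUndefinedError):
            coarticulation_score(structure([0, 0, 0, 0], [0, 0, 0]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        peaks=st.lists(st.floats(1.0, 100.0), min_size=4, max_size=4),
        fracs=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
        c=st.floats(0.01, 50.0),
    )
    def test_bounds_and_homogeneity(self, peaks, fracs, c):
        # troughs cannot exceed their flanking peaks
        troughs = [
            fracs[0] * min(peaks[0], peaks[1]),
            fracs[1] * min(peaks[1], peaks[2]),
            fracs[2] * min(peaks[2], peaks[3]),
        ]
        s = coarticulation_score(structure(peaks, troughs))
        assert 0.0 <= s <= 100.0
        scaled = structure([c * p for p in peaks], [c * t for t in troughs])
        assert coarticulation_score(scaled) == pytest.approx(s, rel=1e-9)


class TestPeakStructure:
    def test_four_separated_bells(self):
        vp = multi_bell_profile([20, 18, 22, 17])
        ps = find_peak_structure(vp)
        assert ps.n_real_peaks == 4
        assert not ps.substitutions
        heights = sorted(h for _, h in ps.peaks)
        assert heights == pytest.approx(sorted([20, 18, 22, 17]), rel=0.02)
        assert all(h == 0.0 for _, h in ps.troughs.values())

    def test_exhaustive_scan_oracle(self):
        """Peaks/troughs equal an exhaustive local-extrema scan."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            heights = rng.uniform(10, 30, 4)
            vp = multi_bell_profile(heights, pad=20, gap=int(rng.integers(8, 30)))
            ps = find_peak_structure(vp)
            v = vp.v
            maxima = [
                i for i in range(1, len(v) - 1) if v[i] >= v[i - 1] and v[i] > v[i + 1]
            ]
            maxima = sorted(sorted(maxima, key=lambda i: -v[i])[:4])
            assert [i for i, _ in ps.peaks] == maxima
            for (a, _), (b, _), k in zip(ps.peaks[:-1], ps.peaks[1:], (1, 2, 3)):
                j = a + int(np.argmin(v[a : b + 1]))
                assert ps.troughs[k][1] == pytest.approx(v[j])

    def test_more_than_four_keeps_largest(self):
        vp = multi_bell_profile([20, 6, 18, 22, 17])
        ps = find_peak_structure(vp)
        assert ps.n_real_peaks == 4
        assert sorted(h for _, h in ps.peaks) == pytest.approx(
            sorted([20, 18, 22, 17]), rel=0.02
        )

    def test_no_peaks_is_undefined(self):
        vp = VelocityProfile(t=np.arange(10) * DT, v=np.linspace(0, 1, 10))
        with pytest.raises(MeasureUndefinedError):
            find_peak_structure(vp)

    def test_merged_pair_substitutes(self, layout, full_curve):
        """Past the merge overlap the structure reports 3 real peaks plus
        one substitution whose height lies between trough and peak."""
        from coartkin.minjerk import grid_profile, solve_via_points

        o = 0.53  # beyond the 4->3 transition of the sweep
        via = solve_via_points(layout, o)
        traj, score, _, n_pk = grid_profile(layout, o, via)
        assert n_pk == 3
        vp = VelocityProfile(traj.t, traj.speed)
        ps = find_peak_structure(vp)
        assert ps.n_real_peaks == 3
        assert len(ps.substitutions) == 1
        (ordinal, (_, tr_h, pk_h)), = ps.substitutions.items()
        assert ordinal in (1, 3)
        assert 0 < tr_h <= pk_h <= max(h for _, h in ps.peaks)


class TestCountPeaks:
    def test_monotone_profile_single_peak(self):
        vp = multi_bell_profile([20.0])
        assert count_velocity_peaks(vp) == 1

    def test_four_bells(self):
        assert count_velocity_peaks(multi_bell_profile([20, 18, 22, 17])) == 4


class TestPathOffset:
    def test_on_path_is_zero(self, layout):
        wp = layout.waypoints()
        xy = np.concatenate(
            [np.linspace(wp[i], wp[i + 1], 60) for i in range(4)]
        )
        assert path_offset_xy(xy, layout) == pytest.approx(0.0, abs=1e-12)

    def test_semicircle_detour_matches_quadrature_oracle(self, layout):
        # semicircular arc over A-B, the rest exactly on the segments
        wp = layout.waypoints()
        a, b = wp[0], wp[1]
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        normal = np.array([-half[1], half[0]])
        theta = np.linspace(np.pi, 0, 400)
        arc = mid + np.outer(np.cos(theta), half) + np.outer(np.sin(theta), normal)
        rest = np.concatenate([np.linspace(wp[i], wp[i + 1], 400) for i in range(1, 4)])
        xy = np.concatenate([arc, rest])
        segments = [LineString([p0, p1]) for p0, p1 in layout.segments()]
        oracle = np.mean(
            [min(seg.distance(Point(p)) for seg in segments) for p in xy]
        )
        assert path_offset_xy(xy, layout) == pytest.approx(oracle, rel=1e-9)

    def test_rigid_transform_invariance(self, layout):
        rng = np.random.default_rng(2)
        xy = rng.normal(5, 4, (300, 2))
        theta, shift = 0.7, np.array([3.0, -2.0])
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        from coartkin.layout import Target, TargetLayout

        moved = TargetLayout(
            [Target(t.label, R @ t.center + shift) for t in layout.targets],
            layout.diameter_mm,
        )
        assert path_offset_xy(xy @ R.T + shift, moved) == pytest.approx(
            path_offset_xy(xy, layout), rel=1e-9
        )


class TestSpatialError:
    def path_through(self, layout, detour_radius_cm=None):
        """Dense polyline through all targets; optionally arcs around B."""
        wp = layout.waypoints()
        parts = []
        for i in range(4):
            parts.append(np.linspace(wp[i], wp[i + 1], 500))
        return np.concatenate(parts)

    def test_through_all_targets_is_zero(self, layout):
        assert spatial_error_xy(self.path_through(layout), layout) == 0.0

    @pytest.mark.parametrize("excess_mm", [0.5, 1.0, 3.0])
    def test_arc_miss_geometry(self, layout, excess_mm):
        """Replace the corner at B with an arc of controlled clearance."""
        radius_mm = layout.diameter_mm / 2.0
        r_cm = (radius_mm + excess_mm) / 10.0
        wp = layout.waypoints()
        b = wp[1]
        theta = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        ring = b + r_cm * np.column_stack([np.cos(theta), np.sin(theta)])
        rest = np.concatenate(
            [np.linspace(wp[i], wp[i + 1], 400) for i in (2, 3)]
        )  # hits C, D, A exactly while staying far from B
        xy = np.concatenate([ring, rest])
        assert spatial_error_xy(xy, layout) == pytest.approx(excess_mm, abs=1e-6)

    def test_tangent_touch_contributes_zero(self, layout):
        # a vertical line tangent to B's disc: closest approach == radius
        radius_cm = layout.diameter_mm / 20.0
        b = layout.center("B")
        tangent = np.linspace(
            b + [radius_cm, -3.0], b + [radius_cm, 3.0], 1001
        )  # midpoint is exactly on the disc edge
        others = np.concatenate(
            [
                np.linspace(layout.center("A"), layout.center("C"), 300),
                np.linspace(layout.center("C"), layout.center("D"), 300),
                np.linspace(layout.center("D"), layout.center("A"), 300),
            ]
        )
        xy = np.concatenate([tangent, others])
        assert spatial_error_xy(xy, layout) == pytest.approx(0.0, abs=1e-9)


class TestNormalization:
    def test_duration_percent_improvement(self):
        assert normalize_duration(1.466, 2.00) == pytest.approx(26.7)
        assert normalize_duration(2.0, 2.0) == 0.0
        assert normalize_duration(2.5, 2.0) < 0  # worsening is negative

    def test_duration_needs_positive_baseline(self):
        with pytest.raises(ValueError):
            normalize_duration(1.0, 0.0)

    def test_score_difference(self):
        assert normalize_score(26.0, 5.0) == 21.0
        assert normalize_score(5.0, 5.0) == 0.0
        assert normalize_score(3.0, 9.0) == -normalize_score(9.0, 3.0)


def test_analyze_trial_flags_gapped_recording(layout):
    t = np.concatenate([np.arange(100), np.arange(100) + 100 + 0.3 * 160]) / 160.0
    from conftest import make_trial

    row = analyze_trial(make_trial(t, t, t), layout)
    assert row["excluded"]
    assert "discontinuous" in row["exclude_reason"]
    assert np.isnan(row["coart_score"])
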