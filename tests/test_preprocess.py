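"""Tests for geometry conversion, blink handling, precision, and QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fractalgaze.errors import (
    InvalidGeometryError,
    InvalidInputError,
    NotEstimableError,
)
from fractalgaze.preprocess import (
    GazeSegment,
    QCThresholds,
    ScreenGeometry,
    Session,
    amplitude_series,
    apply_qc,
    degrees_to_px,
    detect_blinks,
    estimate_precision,
    interpolate_blinks,
    longest_contiguous_run,
    px_to_degrees,
)

from _oracles import naive_precision_per_axis

GEOM = ScreenGeometry()
DT = 1000.0 / 300.0


def make_segment(
    n=300,
    valid=None,
    x=None,
    y=None,
    condition="Social",
    rate=300.0,
    **ids,
):
    """Segment factory: constant central gaze by default."""
    t = np.arange(n) * (1000.0 / rate)
    x = np.full(n, 960.0) if x is None else np.asarray(x, dtype=float)
    y = np.full(n, 540.0) if y is None else np.asarray(y, dtype=float)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    xx = np.where(valid, x, np.nan)
    yy = np.where(valid, y, np.nan)
    defaults = dict(
        person_id="p1", visit_id="v1", movie_id="m1", segment_index=0
    )
    defaults.update(ids)
    return GazeSegment(
        t_ms=t,
        left_x=xx,
        left_y=yy,
        right_x=xx.copy(),
        right_y=yy.copy(),
        left_valid=valid.copy(),
        right_valid=valid.copy(),
        condition=condition,
        nominal_rate_hz=rate,
        **defaults,
    )


class TestGeometry:
    def test_screen_center_maps_to_zero_degrees(self):
        x_deg, y_deg = px_to_degrees((960.0, 540.0), GEOM)
        assert x_deg == pytest.approx(0.0) and y_deg == pytest.approx(0.0)

    def test_round_trip_px_deg_px(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform([0, 0], [1920, 1080], size=(50, 2))
        deg = px_to_degrees((pts[:, 0], pts[:, 1]), GEOM)
        back = degrees_to_px(deg, GEOM)
        assert np.allclose(back[0], pts[:, 0], atol=1e-9)
        assert np.allclose(back[1], pts[:, 1], atol=1e-9)

    def test_screen_edge_subtends_half_width_angle(self):
        # geometry is constructed from the 43.6 deg total subtense, so the
        # right edge must sit at exactly +21.8 deg by the arctan model
        x_deg, _ = px_to_degrees((1920.0, 540.0), GEOM)
        assert x_deg == pytest.approx(21.8, abs=1e-9)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidGeometryError):
            ScreenGeometry(viewing_distance_cm=0.0)
        with pytest.raises(InvalidGeometryError):
            ScreenGeometry(width_deg=200.0)


class TestDetectBlinks:
    def test_all_valid_gives_no_blinks(self):
        assert detect_blinks(make_segment()) == []

    def test_150ms_gap_with_valid_flanks_is_one_blink(self):
        valid = np.ones(300, dtype=bool)
        valid[100:145] = False  # 45 samples ~ 150 ms span < 200
        seg = make_segment(valid=valid)
        assert detect_blinks(seg) == [(100, 144)]

    def test_250ms_gap_is_not_a_blink(self):
        valid = np.ones(300, dtype=bool)
        valid[100:175] = False  # 75 samples ~ 250 ms
        assert detect_blinks(make_segment(valid=valid)) == []

    def test_gap_touching_edge_is_not_a_blink(self):
        valid = np.ones(300, dtype=bool)
        valid[:20] = False
        valid[290:] = False
        assert detect_blinks(make_segment(valid=valid)) == []

    def test_empty_segment_rejected_at_construction(self):
        with pytest.raises(InvalidInputError):
            make_segment(n=0)


class TestInterpolateBlinks:
    def test_no_blinks_leaves_segment_unchanged(self):
        seg = make_segment()
        out, prop, resid = interpolate_blinks(seg, [])
        assert prop == 0.0 and resid == 0.0
        assert np.array_equal(out.left_x, seg.left_x)

    def test_linear_fill_between_flanking_values(self):
        x = np.full(10, 100.0)
        x[4] = 104.0
        valid = np.ones(10, dtype=bool)
        valid[1:4] = False
        x[0] = 100.0
        seg = make_segment(n=10, valid=valid, x=x)
        out, prop, _ = interpolate_blinks(seg, [(1, 3)])
        assert np.allclose(out.left_x[1:4], [101.0, 102.0, 103.0])
        assert out.sample_valid.all()
        assert prop == pytest.approx(0.3)

    def test_proportion_is_fraction_of_samples(self):
        valid = np.ones(200, dtype=bool)
        valid[50:60] = False
        seg = make_segment(n=200, valid=valid)
        _, prop, _ = interpolate_blinks(seg, [(50, 59)])
        assert prop == pytest.approx(0.05)

    def test_residual_missing_reported(self):
        valid = np.ones(200, dtype=bool)
        valid[50:130] = False  # too long: left as residual missing
        seg = make_segment(n=200, valid=valid)
        out, prop, resid = interpolate_blinks(seg, detect_blinks(seg))
        assert prop == 0.0 and resid == pytest.approx(0.4)

    def test_out_of_range_indices_rejected(self):
        seg = make_segment(n=50)
        with pytest.raises(InvalidInputError):
            interpolate_blinks(seg, [(0, 5)])

    def test_interpolated_values_bounded_by_flanks(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(100, 900, size=60)
        valid = np.ones(60, dtype=bool)
        valid[20:40] = False
        seg = make_segment(n=60, valid=valid, x=x)
        out, _, _ = interpolate_blinks(seg, [(20, 39)])
        lo, hi = sorted([x[19], x[40]])
        assert np.all(out.left_x[20:40] >= lo - 1e-12)
        assert np.all(out.left_x[20:40] <= hi + 1e-12)


def _cue_segment_with_angles(x_deg_seq, y_deg_seq, **kw):
    x_px, y_px = degrees_to_px((np.asarray(x_deg_seq), np.asarray(y_deg_seq)), GEOM)
    return make_segment(
        n=len(x_deg_seq), x=x_px, y=y_px, condition="AttentionCue", **kw
    )


class TestEstimatePrecision:
    def test_constant_gaze_has_zero_imprecision(self):
        seg = make_segment(condition="AttentionCue")
        assert estimate_precision([seg], GEOM) == pytest.approx(0.0)

    def test_matches_bruteforce_rms_oracle(self):
        rng = np.random.default_rng(5)
        xd = rng.normal(0, 0.3, size=80)
        yd = rng.normal(0, 0.1, size=80)
        seg = _cue_segment_with_angles(xd, yd)
        got = estimate_precision([seg], GEOM)
        assert got == pytest.approx(naive_precision_per_axis(xd, yd), rel=1e-9)

    def test_alternating_one_axis_jitter(self):
        d = 0.4
        xd = np.resize([d, -d], 60)
        yd = np.zeros(60)
        seg = _cue_segment_with_angles(xd, yd)
        # successive diffs are +/- 2d on x, 0 on y -> per-axis average d
        assert estimate_precision([seg], GEOM) == pytest.approx(d, rel=1e-9)

    def test_doubling_jitter_doubles_estimate(self):
        rng = np.random.default_rng(6)
        xd = rng.normal(0, 0.2, size=100)
        yd = rng.normal(0, 0.2, size=100)
        p1 = estimate_precision([_cue_segment_with_angles(xd, yd)], GEOM)
        p2 = estimate_precision([_cue_segment_with_angles(2 * xd, 2 * yd)], GEOM)
        assert p2 == pytest.approx(2 * p1, rel=1e-9)

    def test_no_usable_trial_raises(self):
        valid = np.zeros(50, dtype=bool)
        seg = make_segment(n=50, valid=valid, condition="AttentionCue")
        with pytest.raises(NotEstimableError):
            estimate_precision([seg], GEOM)


class TestLongestRun:
    def test_fully_valid_returns_whole_segment(self):
        seg = make_segment(n=120)
        run = longest_contiguous_run(seg)
        assert run.n_samples == 120

    def test_longest_of_two_runs_wins(self):
        valid = np.ones(1600, dtype=bool)
        valid[300:400] = False  # runs of 300 and 1200
        run = longest_contiguous_run(make_segment(n=1600, valid=valid))
        assert run.n_samples == 1200
        assert run.t_ms[0] == pytest.approx(400 * DT)

    def test_tie_broken_by_earliest_start(self):
        valid = np.ones(201, dtype=bool)
        valid[100] = False  # two runs of 100
        run = longest_contiguous_run(make_segment(n=201, valid=valid))
        assert run.n_samples == 100 and run.t_ms[0] == 0.0

    def test_no_valid_samples_gives_empty_run(self):
        valid = np.zeros(50, dtype=bool)
        run = longest_contiguous_run(make_segment(n=50, valid=valid))
        assert run.n_samples == 0


class TestAmplitudeSeries:
    def test_stationary_gaze_gives_zero_series(self):
        amp = amplitude_series(make_segment(n=50))
        assert amp.n == 49 and np.allclose(amp.values, 0.0)

    def test_three_four_five_displacement(self):
        x = np.array([100.0, 103.0])
        y = np.array([200.0, 204.0])
        amp = amplitude_series(make_segment(n=2, x=x, y=y))
        assert amp.values[0] == pytest.approx(5.0)

    def test_length_is_pairwise(self):
        assert amplitude_series(make_segment(n=1001)).n == 1000

    def test_non_monotone_timestamps_rejected_at_construction(self):
        with pytest.raises(InvalidInputError):
            GazeSegment(
                t_ms=[0.0, 1.0, 1.0],
                left_x=[0, 0, 0],
                left_y=[0, 0, 0],
                right_x=[0, 0, 0],
                right_y=[0, 0, 0],
                left_valid=[True] * 3,
                right_valid=[True] * 3,
                person_id="p",
                visit_id="v",
                movie_id="m",
                condition="Social",
                segment_index=0,
            )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        shift=st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
        scale=st.floats(min_value=0.1, max_value=50.0),
    )
    def test_time_shift_invariance_and_coordinate_homogeneity(self, shift, scale):
        rng = np.random.default_rng(11)
        x = 500 + np.cumsum(rng.normal(size=40))
        y = 300 + np.cumsum(rng.normal(size=40))
        base = amplitude_series(make_segment(n=40, x=x, y=y))
        shifted = make_segment(n=40, x=x, y=y)
        shifted.t_ms = shifted.t_ms + shift
        assert np.allclose(
            amplitude_series(shifted).values, base.values, rtol=1e-9, atol=1e-12
        )
        scaled = amplitude_series(make_segment(n=40, x=scale * x, y=scale * y))
        assert np.allclose(scaled.values, scale * base.values, rtol=1e-9)


def _session_with(segments, person="p1", visit="v1", add_cue=True):
    segs = list(segments)
    if add_cue:
        segs.append(
            make_segment(
                n=1500,
                condition="AttentionCue",
                person_id=person,
                visit_id=visit,
                movie_id="cue_1",
            )
        )
    for s in segs:
        s.person_id, s.visit_id = person, visit
    return Session(person_id=person, visit_id=visit, segments=segs)


class TestApplyQC:
    def test_min_length_rule_attributed_correctly(self):
        segs = [
            make_segment(n=1000, movie_id="m1"),  # series 999 -> drop
            make_segment(n=1001, movie_id="m2"),  # series 1000 -> keep
            make_segment(n=2001, movie_id="m3"),  # keep
        ]
        series, meta, report = apply_qc([_session_with(segs)])
        assert len(series) == 3  # cue trial also survives
        assert report.count("min_length") == 1
        assert {d["movie_id"] for d in report.decisions} == {"m1"}

    def test_poor_precision_drops_whole_session(self):
        xd = np.resize([0.65, -0.65], 1500)  # per-axis RMS diff 1.3 on both axes
        bad_cue = _cue_segment_with_angles(xd, xd, movie_id="cue_1")
        segs = [make_segment(n=1500, movie_id="m1"), bad_cue]
        sess = Session(person_id="p9", visit_id="v9", segments=segs)
        series, meta, report = apply_qc([sess])
        assert series == []
        assert report.count("precision") == 1
        assert report.excluded_visits == 1 and report.excluded_persons == 1
        assert report.decisions[0]["value"] > 1.21

    def test_interpolation_proportion_rule(self):
        valid = np.ones(1500, dtype=bool)
        # four 45-sample blinks: proportion 180/1500 = 0.12 > 0.115
        for start in (100, 300, 500, 700):
            valid[start : start + 45] = False
        seg = make_segment(n=1500, valid=valid, movie_id="m1")
        series, meta, report = apply_qc([_session_with([seg])])
        assert report.count("interpolation_proportion") == 1
        assert {d["movie_id"] for d in report.decisions} == {"m1"}

    def test_qc_is_idempotent_on_its_own_output(self):
        from fractalgaze.io import segments_to_sessions
        from fractalgaze.synth import SessionSpec, generate_gaze_session

        sess, _, _ = generate_gaze_session(SessionSpec(dropout_fraction=0.0, seed=2))
        series, meta, report, kept = apply_qc([sess], keep_segments=True)
        again_series, again_meta, again_report = apply_qc(
            segments_to_sessions(kept)
        )
        assert len(again_series) == len(series)
        assert not any(d for d in again_report.decisions)

    def test_empty_dataset_is_not_an_error(self):
        series, meta, report = apply_qc([])
        assert series == [] and meta.empty
        assert report.excluded_persons == 0

    def test_adaptive_thresholds_are_computed_and_recorded(self):
        sessions = []
        for i, extra in enumerate((0, 1, 2, 8)):
            valid = np.ones(1500, dtype=bool)
            for b in range(extra):
                valid[100 + 60 * b : 145 + 60 * b] = False
            seg = make_segment(n=1500, valid=valid, movie_id="m1")
            sessions.append(_session_with([seg], person=f"p{i}", visit=f"v{i}"))
        th = QCThresholds(interp_mode="quantile", interp_quantile=0.8)
        series, meta, report = apply_qc(sessions, th)
        recorded = report.thresholds["interp_prop"]
        assert 0 < recorded < 0.2
        # exactly the segments above the dataset-derived cut are excluded
        dropped = [d for d in report.decisions
                   if d["reason"] == "interpolation_proportion"]
        assert dropped and all(d["value"] > recorded for d in dropped)
        assert len(series) + len(dropped) == 8  # 4 test + 4 cue segments

    def test_counts_balance_against_input(self):
        from fractalgaze.synth import SessionSpec, generate_gaze_session

        sessions = []
        for seed in range(3):
            s, _, _ = generate_gaze_session(SessionSpec(
                person_id=f"p{seed}", visit_id=f"v{seed}", seed=seed))
            sessions.append(s)
        series, meta, report = apply_qc(sessions)
        n_input = sum(len(s.segments) for s in sessions)
        assert len(series) + report.excluded_series == n_input
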