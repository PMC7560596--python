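"""Raw eye-tracking samples -> QC-filtered gaze-amplitude time-series.

The preprocessing chain mirrors a stringent infant eye-tracking protocol:

1. **Precision screen** (per session): RMS of successive-sample angular
   displacement during attention-cue trials; sessions with poor precision
   are dropped whole, because recording jitter is itself variability and
   would contaminate a fractal analysis.
2. **Blink interpolation** (per segment): validity gaps shorter than 200 ms
   flanked by valid samples are filled linearly per coordinate.
3. **Interpolation-proportion filter**: segments with too much interpolated
   data are dropped (too much aggregation biases DFA).
4. **Longest contiguous run**: residual missing data still break a segment;
   the longest valid run is kept.
5. **Amplitude series**: per consecutive sample pair, the Euclidean gaze
   displacement D = sqrt((X2-X1)^2 + (Y2-Y1)^2) divided by the elapsed
   time T, yielding the D/T series DFA consumes.
6. **Minimum-length filter**: series with fewer than 1000 points are
   dropped (DFA is not validated below that).

Coordinates are 0-based pixels, origin at the display's top-left corner.
Left/right eyes are averaged when both are valid, otherwise the single
valid eye is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidGeometryError,
    InvalidInputError,
    NotEstimableError,
)

CONDITIONS = ("Social", "Pixelated", "AttentionCue")


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry needed to convert pixels to degrees of visual angle.

    ``width_deg`` is the total horizontal visual angle the display subtends
    at the given viewing distance; the physical pixel pitch is derived from
    it, so only relative (not absolute) physical sizes are assumed.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_deg: float = 43.6
    viewing_distance_cm: float = 65.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidGeometryError("pixel dimensions must be positive")
        if not 0 < self.width_deg < 180:
            raise InvalidGeometryError("width_deg must be in (0, 180)")
        if self.viewing_distance_cm <= 0:
            raise InvalidGeometryError("viewing distance must be positive")

    @property
    def cm_per_px(self) -> float:
        half_width_cm = self.viewing_distance_cm * np.tan(
            np.deg2rad(self.width_deg / 2.0)
        )
        return 2.0 * half_width_cm / self.width_px


def px_to_degrees(
    point_px: tuple[float, float] | np.ndarray,
    geometry: ScreenGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis visual angle of a pixel position relative to screen center.

    Uses the exact arctangent model: the angle whose tangent is the
    physical offset from center over the viewing distance.  Exact at all
    eccentricities; reduces to the small-angle linear form near center.
    Accepts scalars or arrays.
    """
    x_px, y_px = point_px[0], point_px[1]
    cx = geometry.width_px / 2.0
    cy = geometry.height_px / 2.0
    dx_cm = (np.asarray(x_px, float) - cx) * geometry.cm_per_px
    dy_cm = (np.asarray(y_px, float) - cy) * geometry.cm_per_px
    x_deg = np.rad2deg(np.arctan2(dx_cm, geometry.viewing_distance_cm))
    y_deg = np.rad2deg(np.arctan2(dy_cm, geometry.viewing_distance_cm))
    return x_deg, y_deg


def degrees_to_px(
    point_deg: tuple[float, float] | np.ndarray,
    geometry: ScreenGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`px_to_degrees` (round-trips to float precision)."""
    x_deg, y_deg = point_deg[0], point_deg[1]
    dx_cm = geometry.viewing_distance_cm * np.tan(np.deg2rad(np.asarray(x_deg, float)))
    dy_cm = geometry.viewing_distance_cm * np.tan(np.deg2rad(np.asarray(y_deg, float)))
    x_px = dx_cm / geometry.cm_per_px + geometry.width_px / 2.0
    y_px = dy_cm / geometry.cm_per_px + geometry.height_px / 2.0
    return x_px, y_px


# ---------------------------------------------------------------------------
# data containers


@dataclass
class GazeSegment:
    """Ordered eye-tracker samples for one movie segment.

    Missing coordinates are NaN with the matching validity flag False.
    ``interpolated`` marks samples filled in by blink interpolation.
    """

    t_ms: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    left_valid: np.ndarray
    right_valid: np.ndarray
    person_id: str
    visit_id: str
    movie_id: str
    condition: str
    segment_index: int
    nominal_rate_hz: float = 300.0
    interpolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InvalidInputError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        if self.t_ms.size < 1:
            raise InvalidInputError("segment must contain at least one sample")
        if np.any(np.diff(self.t_ms) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        for attr in ("left_x", "left_y", "right_x", "right_y"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        self.left_valid = np.asarray(self.left_valid, dtype=bool)
        self.right_valid = np.asarray(self.right_valid, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.t_ms.size, dtype=bool)

    @property
    def n_samples(self) -> int:
        return int(self.t_ms.size)

    @property
    def sample_valid(self) -> np.ndarray:
        """A sample is usable if at least one eye is valid."""
        return self.left_valid | self.right_valid

    def combined_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Cyclopean gaze point: average of valid eyes, single eye otherwise."""
        both = self.left_valid & self.right_valid
        x = np.where(
            both,
            0.5 * (self.left_x + self.right_x),
            np.where(self.left_valid, self.left_x, self.right_x),
        )
        y = np.where(
            both,
            0.5 * (self.left_y + self.right_y),
            np.where(self.left_valid, self.left_y, self.right_y),
        )
        x = np.where(self.sample_valid, x, np.nan)
        y = np.where(self.sample_valid, y, np.nan)
        return x, y


@dataclass
class Session:
    """All segments recorded at one lab visit of one person."""

    person_id: str
    visit_id: str
    segments: list[GazeSegment]
    age_months: float | None = None

    def attention_trials(self) -> list[GazeSegment]:
        return [s for s in self.segments if s.condition == "AttentionCue"]


@dataclass(frozen=True)
class AmplitudeSeries:
    """The D/T displacement-magnitude series for one contiguous gaze run."""

    values: np.ndarray
    dt_units: str
    person_id: str
    visit_id: str
    movie_id: str
    condition: str
    segment_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise InvalidInputError("amplitude values must be non-negative")

    @property
    def n(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# blink handling


def detect_blinks(
    segment: GazeSegment, max_blink_ms: float = 200.0
) -> list[tuple[int, int]]:
    """Locate blink gaps: short invalid runs flanked by valid samples.

    A blink is a maximal run of invalid samples whose spanned duration —
    measured from the last valid sample before the run to the first valid
    sample after it — is below ``max_blink_ms``.  Runs touching the
    segment edges, or lasting longer, are residual missing data, not
    blinks.  Returns ``(start_idx, end_idx)`` inclusive index pairs.
    """
    if segment.n_samples == 0:
        raise InvalidInputError("empty segment")
    valid = segment.sample_valid
    blinks: list[tuple[int, int]] = []
    n = valid.size
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        # run [i, j-1]; needs valid flanks at i-1 and j
        if i > 0 and j < n:
            duration = segment.t_ms[j] - segment.t_ms[i - 1]
            if duration < max_blink_ms:
                blinks.append((i, j - 1))
        i = j
    return blinks


def interpolate_blinks(
    segment: GazeSegment, blinks: Sequence[tuple[int, int]]
) -> tuple[GazeSegment, float, float]:
    """Fill blink gaps linearly in time between the flanking valid samples.

    Returns ``(segment', proportion_interpolated, residual_missing)`` where
    both proportions are relative to the total sample count.  The flanking
    samples themselves are unchanged.  Each eye is interpolated from its
    own flanking values; an eye invalid on a flank stays missing for that
    gap.
    """
    n = segment.n_samples
    new = replace(
        segment,
        left_x=segment.left_x.copy(),
        left_y=segment.left_y.copy(),
        right_x=segment.right_x.copy(),
        right_y=segment.right_y.copy(),
        left_valid=segment.left_valid.copy(),
        right_valid=segment.right_valid.copy(),
        interpolated=segment.interpolated.copy(),
    )
    n_interp = 0
    for start, end in blinks:
        if not (0 < start <= end < n - 1):
            raise InvalidInputError(f"blink indices ({start}, {end}) out of range")
        lo, hi = start - 1, end + 1
        t = segment.t_ms
        for valid, xs, ys in (
            (new.left_valid, new.left_x, new.left_y),
            (new.right_valid, new.right_x, new.right_y),
        ):
            if not (valid[lo] and valid[hi]):
                continue
            frac = (t[start : end + 1] - t[lo]) / (t[hi] - t[lo])
            xs[start : end + 1] = xs[lo] + frac * (xs[hi] - xs[lo])
            ys[start : end + 1] = ys[lo] + frac * (ys[hi] - ys[lo])
            valid[start : end + 1] = True
        if new.sample_valid[start : end + 1].any():
            new.interpolated[start : end + 1] = True
            n_interp += end - start + 1
    proportion = n_interp / n
    residual_missing = float(np.mean(~new.sample_valid))
    return new, proportion, residual_missing


# ---------------------------------------------------------------------------
# precision


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, stop) of the longest True run; earliest wins ties; stop exclusive."""
    best_start, best_len = 0, 0
    i, n = 0, mask.size
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        if j - i > best_len:
            best_start, best_len = i, j - i
        i = j
    return best_start, best_start + best_len


def estimate_precision(
    attention_trials: Iterable[GazeSegment],
    geometry: ScreenGeometry,
    mode: Literal["per_axis", "euclidean"] = "per_axis",
) -> float:
    """Recording precision: RMS successive-sample displacement, in degrees.

    For each attention-cue trial, the longest contiguous run of raw valid
    samples is taken and, for each eye present in the run, the root mean
    square of successive-sample angular displacement is computed per axis.
    The default averages those per-axis, per-eye RMS values; the
    ``euclidean`` alternative uses 2-D displacement magnitudes per eye
    (both readings of "averaged across X and Y axes for both eyes" are
    implemented).  Trial-level values are then averaged.
    """
    per_trial: list[float] = []
    for trial in attention_trials:
        start, stop = _longest_true_run(trial.sample_valid)
        if stop - start < 2:
            continue
        eye_vals: list[float] = []
        for valid, xs, ys in (
            (trial.left_valid, trial.left_x, trial.left_y),
            (trial.right_valid, trial.right_x, trial.right_y),
        ):
            ok = valid[start:stop]
            if ok.sum() < 2:
                continue
            x_deg, y_deg = px_to_degrees((xs[start:stop][ok], ys[start:stop][ok]), geometry)
            dx, dy = np.diff(x_deg), np.diff(y_deg)
            if mode == "per_axis":
                eye_vals.append(
                    0.5 * (np.sqrt(np.mean(dx**2)) + np.sqrt(np.mean(dy**2)))
                )
            else:
                eye_vals.append(float(np.sqrt(np.mean(dx**2 + dy**2))))
        if eye_vals:
            per_trial.append(float(np.mean(eye_vals)))
    if not per_trial:
        raise NotEstimableError(
            "no attention-cue trial with >= 2 valid consecutive samples"
        )
    return float(np.mean(per_trial))


# ---------------------------------------------------------------------------
# run extraction and amplitude series


def longest_contiguous_run(segment: GazeSegment) -> GazeSegment:
    """The longest run of valid-after-interpolation samples (earliest on ties).

    Residual missing samples break runs.  Returns a (possibly empty) view
    of the segment restricted to the winning run.
    """
    start, stop = _longest_true_run(segment.sample_valid)
    return replace(
        segment,
        t_ms=segment.t_ms[start:stop],
        left_x=segment.left_x[start:stop],
        left_y=segment.left_y[start:stop],
        right_x=segment.right_x[start:stop],
        right_y=segment.right_y[start:stop],
        left_valid=segment.left_valid[start:stop],
        right_valid=segment.right_valid[start:stop],
        interpolated=segment.interpolated[start:stop],
    ) if stop > start else _empty_like(segment)


def _empty_like(segment: GazeSegment) -> GazeSegment:
    seg = GazeSegment.__new__(GazeSegment)
    for attr in ("left_x", "left_y", "right_x", "right_y"):
        setattr(seg, attr, np.empty(0))
    seg.t_ms = np.empty(0)
    seg.left_valid = np.empty(0, dtype=bool)
    seg.right_valid = np.empty(0, dtype=bool)
    seg.interpolated = np.empty(0, dtype=bool)
    seg.person_id = segment.person_id
    seg.visit_id = segment.visit_id
    seg.movie_id = segment.movie_id
    seg.condition = segment.condition
    seg.segment_index = segment.segment_index
    seg.nominal_rate_hz = segment.nominal_rate_hz
    return seg


def amplitude_series(run: GazeSegment, nominal_rate_hz: float | None = None) -> AmplitudeSeries:
    """Per-interval gaze displacement magnitude D/T.

    D is the Euclidean displacement of the eye-averaged gaze point between
    consecutive samples; T is the timestamp difference expressed in nominal
    sample intervals (1 interval = 1/rate seconds), so a one-sample step
    has T = 1.  The scaling exponent downstream is invariant to this unit
    choice.  Output length is run length - 1.
    """
    rate = nominal_rate_hz or run.nominal_rate_hz
    if run.n_samples < 2:
        raise InvalidInputError("run must contain at least 2 samples")
    x, y = run.combined_xy()
    if np.any(~run.sample_valid):
        raise InvalidInputError("run contains invalid samples")
    dt_ms = np.diff(run.t_ms)
    if np.any(dt_ms <= 0):
        raise InvalidInputError("nonpositive timestamp difference in run")
    t_intervals = dt_ms * rate / 1000.0
    d = np.hypot(np.diff(x), np.diff(y))
    return AmplitudeSeries(
        values=d / t_intervals,
        dt_units=f"sample interval (1/{rate:g} s)",
        person_id=run.person_id,
        visit_id=run.visit_id,
        movie_id=run.movie_id,
        condition=run.condition,
        segment_index=run.segment_index,
    )


# ---------------------------------------------------------------------------
# quality control


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds for the QC stage.

    ``precision_mode="mean+2sd"`` and ``interp_mode="quantile"`` compute
    the threshold from the dataset's own distribution (two standard
    deviations above the mean precision; the 80th percentile of
    interpolation proportions); fixed modes use the values given.
    """

    precision_deg: float = 1.21
    precision_mode: Literal["fixed", "mean+2sd"] = "fixed"
    interp_prop: float = 0.115
    interp_mode: Literal["fixed", "quantile"] = "fixed"
    interp_quantile: float = 0.8
    min_samples: int = 1000


@dataclass
class QCReport:
    """Who was excluded, why, and under which thresholds."""

    thresholds: dict
    decisions: list[dict] = field(default_factory=list)
    excluded_persons: int = 0
    excluded_visits: int = 0
    excluded_series: int = 0

    def count(self, reason: str) -> int:
        return sum(1 for d in self.decisions if d["reason"] == reason)


def apply_qc(
    sessions: Sequence[Session],
    thresholds: QCThresholds | None = None,
    geometry: ScreenGeometry | None = None,
    max_blink_ms: float = 200.0,
    keep_segments: bool = False,
):
    """Run the full QC pipeline over a dataset of sessions.

    Stage order: session precision screen -> blink interpolation ->
    interpolation-proportion filter -> longest contiguous run ->
    amplitude series -> minimum-length filter.  Returns the surviving
    amplitude series, a per-series metadata table (one row per surviving
    series: ids, condition, n, proportions, precision), and a
    :class:`QCReport` tallying every exclusion.  With ``keep_segments``
    the blink-interpolated segments backing each surviving series are
    returned as a fourth element (for AOI tallies on the same samples).
    """
    thresholds = thresholds or QCThresholds()
    geometry = geometry or ScreenGeometry()
    report = QCReport(thresholds={})

    # --- precision per session
    precisions: dict[tuple[str, str], float | None] = {}
    for sess in sessions:
        try:
            precisions[(sess.person_id, sess.visit_id)] = estimate_precision(
                sess.attention_trials(), geometry
            )
        except NotEstimableError:
            precisions[(sess.person_id, sess.visit_id)] = None

    if thresholds.precision_mode == "mean+2sd":
        vals = np.array([p for p in precisions.values() if p is not None])
        prec_cut = float(vals.mean() + 2 * vals.std(ddof=1)) if vals.size > 1 else np.inf
    else:
        prec_cut = thresholds.precision_deg

    surviving_sessions: list[tuple[Session, float | None]] = []
    for sess in sessions:
        prec = precisions[(sess.person_id, sess.visit_id)]
        if prec is None or prec > prec_cut:
            report.decisions.append(
                {
                    "level": "session",
                    "person_id": sess.person_id,
                    "visit_id": sess.visit_id,
                    "reason": "precision",
                    "value": prec,
                    "n_series_lost": len(
                        [s for s in sess.segments]
                    ),
                }
            )
        else:
            surviving_sessions.append((sess, prec))

    # --- blink interpolation + interpolation-proportion filter
    interp_records: list[tuple[Session, float, GazeSegment, float, float]] = []
    for sess, prec in surviving_sessions:
        for seg in sess.segments:
            blinks = detect_blinks(seg, max_blink_ms)
            seg2, prop, resid = interpolate_blinks(seg, blinks)
            interp_records.append((sess, prec, seg2, prop, resid))

    if thresholds.interp_mode == "quantile":
        props = np.array([r[3] for r in interp_records])
        interp_cut = (
            float(np.quantile(props, thresholds.interp_quantile))
            if props.size
            else thresholds.interp_prop
        )
    else:
        interp_cut = thresholds.interp_prop

    kept_after_interp = []
    for sess, prec, seg, prop, resid in interp_records:
        if prop > interp_cut:
            report.decisions.append(
                {
                    "level": "segment",
                    "person_id": seg.person_id,
                    "visit_id": seg.visit_id,
                    "movie_id": seg.movie_id,
                    "segment_index": seg.segment_index,
                    "reason": "interpolation_proportion",
                    "value": prop,
                }
            )
        else:
            kept_after_interp.append((sess, prec, seg, prop, resid))

    # --- longest run, amplitude series, min length
    series_out: list[AmplitudeSeries] = []
    meta_rows: list[dict] = []
    kept_segments: list[GazeSegment] = []
    for sess, prec, seg, prop, resid in kept_after_interp:
        run = longest_contiguous_run(seg)
        n_series = max(run.n_samples - 1, 0)
        if n_series < thresholds.min_samples:
            report.decisions.append(
                {
                    "level": "series",
                    "person_id": seg.person_id,
                    "visit_id": seg.visit_id,
                    "movie_id": seg.movie_id,
                    "segment_index": seg.segment_index,
                    "reason": "min_length",
                    "value": n_series,
                }
            )
            continue
        amp = amplitude_series(run)
        series_out.append(amp)
        kept_segments.append(seg)
        meta_rows.append(
            {
                "person_id": seg.person_id,
                "visit_id": seg.visit_id,
                "movie_id": seg.movie_id,
                "condition": seg.condition,
                "segment_index": seg.segment_index,
                "n": amp.n,
                "proportion_interpolated": prop,
                "residual_missing": resid,
                "longest_run_length": run.n_samples,
                "precision_deg": prec,
            }
        )

    report.thresholds = {
        "precision_deg": prec_cut,
        "precision_mode": thresholds.precision_mode,
        "interp_prop": interp_cut,
        "interp_mode": thresholds.interp_mode,
        "min_samples": thresholds.min_samples,
    }

    # --- person/visit tallies: a visit (person) is excluded when it retains
    # no series at all but contributed input data.
    input_visits = {(s.person_id, s.visit_id) for s in sessions}
    kept_visits = {(r["person_id"], r["visit_id"]) for r in meta_rows}
    input_persons = {s.person_id for s in sessions}
    kept_persons = {p for p, _ in kept_visits}
    report.excluded_visits = len(input_visits - kept_visits)
    report.excluded_persons = len(input_persons - kept_persons)
    report.excluded_series = sum(
        d.get("n_series_lost", 1) for d in report.decisions
    )

    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "person_id",
            "visit_id",
            "movie_id",
            "condition",
            "segment_index",
            "n",
            "proportion_interpolated",
            "residual_missing",
            "longest_run_length",
            "precision_deg",
        ],
    )
    if keep_segments:
        return series_out, meta, report, kept_segments
    return series_out, meta, report
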