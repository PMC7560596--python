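"""Face area-of-interest (AOI) metrics for gaze samples.

Face AOIs are axis-aligned pixel rectangles attached to movie frames
(0 to 3 faces per frame).  Gaze samples are assigned to frames by the
nearest frame at or before the sample timestamp, tested against the
frame's rectangles (half-open: closed on the min edges, open on the max
edges), and tallied into face / non-face counts.  Counts aggregate
upward — movie, visit, person — by summing and recomputing, never by
averaging ratios.

Off-screen samples and invalid samples are excluded from both tallies,
so ``n_face + n_nonface`` always equals the number of valid on-screen
samples.  Both the bounded proportion ``n_face / (n_face + n_nonface)``
and the literal ratio ``n_face / n_nonface`` are reported; downstream
models consume the proportion by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .preprocess import GazeSegment, ScreenGeometry

MAX_FACES_PER_FRAME = 3


@dataclass(frozen=True)
class FaceRect:
    """One face rectangle in pixel coordinates, [x_min, x_max) x [y_min, y_max)."""

    face_id: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidInputError("rectangle must have positive extent")

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass
class AoiTrack:
    """Per-frame face rectangles for one movie.

    ``frames`` maps frame index -> list of rectangles (possibly empty).
    Frame times are ``frame_index / frame_rate_hz`` relative to movie start.
    """

    frames: dict[int, list[FaceRect]]
    frame_rate_hz: float = 30.0
    movie_id: str = ""

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise InvalidInputError("frame rate must be positive")
        for idx, rects in self.frames.items():
            if len(rects) > MAX_FACES_PER_FRAME:
                raise InvalidInputError(
                    f"frame {idx} has {len(rects)} faces (> {MAX_FACES_PER_FRAME})"
                )

    def rects_at(self, t_ms: float) -> list[FaceRect]:
        """Rectangles of the nearest frame at or before ``t_ms`` (exact index)."""
        idx = int(math.floor(t_ms / 1000.0 * self.frame_rate_hz))
        return self.frames.get(idx, [])


def interpolate_aoi_track(
    track: AoiTrack, gaps: Sequence[tuple[int, int]]
) -> AoiTrack:
    """Fill missing frames by linear interpolation of rectangle coordinates.

    ``gaps`` lists inclusive ``(first_missing, last_missing)`` frame-index
    ranges.  For each face id present on both flanking frames, every
    rectangle coordinate is linear in frame index across the gap.  A face
    absent on either flank (e.g. obscured) is not created inside the gap.
    Gaps touching the track edges are left untouched — no extrapolation.
    """
    frames = {idx: list(rects) for idx, rects in track.frames.items()}
    for first, last in gaps:
        lo, hi = first - 1, last + 1
        if lo not in frames or hi not in frames:
            continue  # edge gap: no extrapolation
        lo_faces = {r.face_id: r for r in frames[lo]}
        hi_faces = {r.face_id: r for r in frames[hi]}
        shared = sorted(set(lo_faces) & set(hi_faces))
        for idx in range(first, last + 1):
            frac = (idx - lo) / (hi - lo)
            rects = []
            for fid in shared:
                a, b = lo_faces[fid], hi_faces[fid]
                rects.append(
                    FaceRect(
                        face_id=fid,
                        x_min=a.x_min + frac * (b.x_min - a.x_min),
                        y_min=a.y_min + frac * (b.y_min - a.y_min),
                        x_max=a.x_max + frac * (b.x_max - a.x_max),
                        y_max=a.y_max + frac * (b.y_max - a.y_max),
                    )
                )
            frames[idx] = rects
    return AoiTrack(frames=frames, frame_rate_hz=track.frame_rate_hz, movie_id=track.movie_id)


def sample_in_face(
    sample_xy_px: tuple[float, float], frame_rects: Iterable[FaceRect]
) -> bool:
    """True iff the point lies inside at least one rectangle (half-open)."""
    x, y = sample_xy_px
    return any(r.contains(x, y) for r in frame_rects)


@dataclass(frozen=True)
class FaceLookSummary:
    """Face/non-face sample tallies at one aggregation level."""

    level: str
    keys: dict = field(default_factory=dict)
    n_face: int = 0
    n_nonface: int = 0

    @property
    def proportion(self) -> float:
        total = self.n_face + self.n_nonface
        return self.n_face / total if total else float("nan")

    @property
    def ratio(self) -> float:
        if self.n_nonface == 0:
            return float("inf") if self.n_face else float("nan")
        return self.n_face / self.n_nonface


def _segment_counts(
    segment: GazeSegment, track: AoiTrack, screen: ScreenGeometry
) -> tuple[int, int]:
    x, y = segment.combined_xy()
    valid = segment.sample_valid
    on_screen = (
        valid
        & (x >= 0)
        & (x < screen.width_px)
        & (y >= 0)
        & (y < screen.height_px)
    )
    n_face = 0
    n_total = int(on_screen.sum())
    for t, xi, yi in zip(segment.t_ms[on_screen], x[on_screen], y[on_screen]):
        if sample_in_face((xi, yi), track.rects_at(t)):
            n_face += 1
    return n_face, n_total - n_face


def face_looking(
    segments: Sequence[GazeSegment],
    tracks: Mapping[str, AoiTrack],
    screen: ScreenGeometry | None = None,
    counterpart: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Tally face-looking per segment and roll up to movie/visit/person.

    ``tracks`` maps movie id to its AOI track; ``counterpart`` maps movie
    ids without a track of their own (pixelated versions) to the movie
    whose track they reuse unchanged.  Segments whose movie has no track
    either way (attention cues) are skipped.

    Returns a dict of DataFrames keyed by level (``segment``, ``movie``,
    ``visit``, ``person``); roll-ups sum the counts and recompute the
    ratio and proportion from the summed counts.
    """
    screen = screen or ScreenGeometry()
    counterpart = counterpart or {}
    rows = []
    for seg in segments:
        track = tracks.get(seg.movie_id)
        if track is None and seg.movie_id in counterpart:
            track = tracks.get(counterpart[seg.movie_id])
        if track is None:
            continue
        n_face, n_nonface = _segment_counts(seg, track, screen)
        rows.append(
            {
                "person_id": seg.person_id,
                "visit_id": seg.visit_id,
                "movie_id": seg.movie_id,
                "condition": seg.condition,
                "segment_index": seg.segment_index,
                "n_face": n_face,
                "n_nonface": n_nonface,
            }
        )
    seg_df = pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "visit_id",
            "movie_id",
            "condition",
            "segment_index",
            "n_face",
            "n_nonface",
        ],
    )
    out = {"segment": _finalize(seg_df)}
    for level, keys in (
        ("movie", ["person_id", "visit_id", "movie_id", "condition"]),
        ("visit", ["person_id", "visit_id"]),
        ("person", ["person_id"]),
    ):
        if seg_df.empty:
            out[level] = _finalize(seg_df.reindex(columns=keys + ["n_face", "n_nonface"]))
            continue
        agg = seg_df.groupby(keys, as_index=False)[["n_face", "n_nonface"]].sum()
        out[level] = _finalize(agg)
    return out


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    total = df["n_face"] + df["n_nonface"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["proportion"] = np.where(total > 0, df["n_face"] / total, np.nan)
        df["ratio"] = np.where(
            df["n_nonface"] > 0,
            df["n_face"] / df["n_nonface"],
            np.where(df["n_face"] > 0, np.inf, np.nan),
        )
    return df
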