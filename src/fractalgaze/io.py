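"""File formats, configuration, and end-to-end pipeline orchestration.

All tabular data are delimited text with explicit headers; AOI tracks,
ground truth, and manifests are JSON.  The gaze CSV schema is::

    t_ms, left_x_px, left_y_px, right_x_px, right_y_px,
    left_valid, right_valid, person_id, visit_id, movie_id,
    condition, segment_index

Missing coordinates are empty fields with the matching validity flag 0.
Condition labels are case-sensitive (``Social``, ``Pixelated``,
``AttentionCue``).  Coordinates are 0-based pixels, origin at the display
top-left.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aoi import AoiTrack, FaceRect, face_looking
from .dfa import DFAParams, dfa_alpha, classify_noise
from .errors import InvalidInputError, InvalidSpecError, ParseError
from .models import (
    AlphaModelSpec,
    build_design,
    fit_alpha_model,
    lrt,
    variance_explained,
)
from .preprocess import (
    AmplitudeSeries,
    GazeSegment,
    QCThresholds,
    ScreenGeometry,
    Session,
    apply_qc,
)

logger = logging.getLogger(__name__)

GAZE_CSV_COLUMNS = [
    "t_ms",
    "left_x_px",
    "left_y_px",
    "right_x_px",
    "right_y_px",
    "left_valid",
    "right_valid",
    "person_id",
    "visit_id",
    "movie_id",
    "condition",
    "segment_index",
]

_VALID_CONDITIONS = {"Social", "Pixelated", "AttentionCue"}


# ---------------------------------------------------------------------------
# gaze CSV


def write_gaze_csv(segments: Sequence[GazeSegment], path: str | Path) -> Path:
    """Write segments to the documented gaze CSV schema (lossless)."""
    frames = []
    for seg in segments:
        frames.append(
            pd.DataFrame(
                {
                    "t_ms": seg.t_ms,
                    "left_x_px": seg.left_x,
                    "left_y_px": seg.left_y,
                    "right_x_px": seg.right_x,
                    "right_y_px": seg.right_y,
                    "left_valid": seg.left_valid.astype(int),
                    "right_valid": seg.right_valid.astype(int),
                    "person_id": seg.person_id,
                    "visit_id": seg.visit_id,
                    "movie_id": seg.movie_id,
                    "condition": seg.condition,
                    "segment_index": seg.segment_index,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=GAZE_CSV_COLUMNS)
    )
    path = Path(path)
    # %.17g guarantees exact float64 round-trips through text
    df.to_csv(path, index=False, na_rep="", float_format="%.17g")
    return path


def read_gaze_csv(path: str | Path, nominal_rate_hz: float = 300.0) -> list[GazeSegment]:
    """Read gaze segments from CSV; parse errors name the offending line."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"condition": str}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in GAZE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header lacks columns {missing}")
    if df.empty:
        return []
    bad = df.loc[~df["condition"].isin(_VALID_CONDITIONS)]
    if not bad.empty:
        line = int(bad.index[0]) + 2  # header + 1-based
        raise ParseError(
            f"{path}: line {line}: unknown condition {bad.iloc[0]['condition']!r} "
            "(labels are case-sensitive)"
        )
    segments: list[GazeSegment] = []
    keys = ["person_id", "visit_id", "movie_id", "segment_index"]
    for _, g in df.groupby(keys, sort=False):
        t = g["t_ms"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            row = g.index[int(np.argmax(np.diff(t) <= 0)) + 1]
            raise ParseError(f"{path}: line {row + 2}: non-monotone timestamp")
        lv = g["left_valid"].to_numpy(dtype=float).astype(bool)
        rv = g["right_valid"].to_numpy(dtype=float).astype(bool)
        segments.append(
            GazeSegment(
                t_ms=t,
                left_x=g["left_x_px"].to_numpy(dtype=float),
                left_y=g["left_y_px"].to_numpy(dtype=float),
                right_x=g["right_x_px"].to_numpy(dtype=float),
                right_y=g["right_y_px"].to_numpy(dtype=float),
                left_valid=lv,
                right_valid=rv,
                person_id=str(g.iloc[0]["person_id"]),
                visit_id=str(g.iloc[0]["visit_id"]),
                movie_id=str(g.iloc[0]["movie_id"]),
                condition=str(g.iloc[0]["condition"]),
                segment_index=int(g.iloc[0]["segment_index"]),
                nominal_rate_hz=nominal_rate_hz,
            )
        )
    return segments


def segments_to_sessions(segments: Sequence[GazeSegment]) -> list[Session]:
    """Group segments by (person, visit), preserving first-seen order."""
    by_visit: dict[tuple[str, str], list[GazeSegment]] = {}
    for seg in segments:
        by_visit.setdefault((seg.person_id, seg.visit_id), []).append(seg)
    return [
        Session(person_id=p, visit_id=v, segments=segs)
        for (p, v), segs in by_visit.items()
    ]


# ---------------------------------------------------------------------------
# AOI JSON


def write_aoi_json(tracks: dict[str, AoiTrack], path: str | Path) -> Path:
    payload = {
        movie_id: {
            "movie_id": movie_id,
            "frame_rate_hz": track.frame_rate_hz,
            "frames": [
                {
                    "frame_index": int(idx),
                    "time_ms": idx / track.frame_rate_hz * 1000.0,
                    "rects": [dataclasses.asdict(r) for r in rects],
                }
                for idx, rects in sorted(track.frames.items())
            ],
        }
        for movie_id, track in tracks.items()
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def read_aoi_json(path: str | Path) -> dict[str, AoiTrack]:
    payload = json.loads(Path(path).read_text())
    tracks = {}
    for movie_id, rec in payload.items():
        frames = {
            int(f["frame_index"]): [FaceRect(**r) for r in f["rects"]]
            for f in rec["frames"]
        }
        tracks[movie_id] = AoiTrack(
            frames=frames,
            frame_rate_hz=float(rec.get("frame_rate_hz", 30.0)),
            movie_id=movie_id,
        )
    return tracks


def write_amplitude_series(
    series: Sequence[AmplitudeSeries], out_dir: str | Path
) -> list[Path]:
    """One single-column CSV per series, named by its nesting ids."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in series:
        name = f"{s.person_id}_{s.visit_id}_{s.movie_id}_s{s.segment_index}.csv"
        p = out_dir / name
        pd.DataFrame({"amplitude": s.values}).to_csv(p, index=False)
        paths.append(p)
    return paths


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write a bundle of result tables as headered CSVs named by key."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run (see ``fractalgaze all``)."""

    out_dir: str = "results"
    seed: int = 0
    simulate: dict = field(default_factory=lambda: {"n_persons": 2})
    gaze_csv: str | None = None
    aoi_json: str | None = None
    screen: dict = field(default_factory=dict)
    sampling_rate_hz: float = 300.0
    qc: dict = field(default_factory=dict)
    dfa: dict = field(default_factory=dict)
    allow_short_series: bool = False
    fit_models: bool = True
    verbosity: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except Exception as exc:
        raise InvalidSpecError(f"cannot parse config {path}: {exc}") from exc
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write a results bundle.

    Stages: acquire (simulate or read) -> QC/preprocess -> DFA -> AOI ->
    models.  Each stage's retained/excluded counts are recorded in
    ``manifest.json``; reruns with the same config and seed are
    reproducible.  Returns the bundle as a dict of in-memory objects.
    """
    from .synth import CohortSpec, generate_cohort, generate_gaze_session

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = ScreenGeometry(**config.screen) if config.screen else ScreenGeometry()
    manifest: dict = {"package": "fractalgaze", "version": __version__, "stages": {}}
    manifest["config"] = dataclasses.asdict(config)

    # --- acquire
    tracks: dict[str, AoiTrack] = {}
    counterpart: dict[str, str] = {}
    ages: dict[tuple[str, str], float] = {}
    if config.gaze_csv:
        segments = read_gaze_csv(config.gaze_csv, config.sampling_rate_hz)
        sessions = segments_to_sessions(segments)
        if config.aoi_json:
            tracks = read_aoi_json(config.aoi_json)
        manifest["stages"]["acquire"] = {
            "mode": "read",
            "segments": len(segments),
            "sessions": len(sessions),
        }
    else:
        sim = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (config.simulate or {}).items()
        }
        sim.setdefault("seed", config.seed)
        cohort_spec = CohortSpec(**sim)
        table, session_specs = generate_cohort(cohort_spec)
        table.to_csv(out / "cohort_truth.csv", index=False)
        sessions = []
        for ss in session_specs:
            sess, truth, sess_tracks = generate_gaze_session(ss)
            ages[(sess.person_id, sess.visit_id)] = sess.age_months
            sessions.append(sess)
            tracks.update(sess_tracks)
        manifest["stages"]["acquire"] = {
            "mode": "simulate",
            "sessions": len(sessions),
            "segments": int(sum(len(s.segments) for s in sessions)),
        }
    counterpart = {
        m: m.replace("pix_", "soc_") for m in tracks if m.startswith("pix_")
    }

    # --- QC / preprocess
    qc_thresholds = QCThresholds(**config.qc) if config.qc else QCThresholds()
    series, meta, report, kept_segments = apply_qc(
        sessions, qc_thresholds, geometry, keep_segments=True
    )
    n_input_segments = sum(len(s.segments) for s in sessions)
    manifest["stages"]["qc"] = {
        "input_segments": n_input_segments,
        "retained_series": len(series),
        "excluded": n_input_segments - len(series),
        "thresholds": report.thresholds,
        "excluded_persons": report.excluded_persons,
        "excluded_visits": report.excluded_visits,
        "excluded_series": report.excluded_series,
    }
    (out / "qc_report.json").write_text(
        json.dumps(
            {
                "thresholds": report.thresholds,
                "excluded_persons": report.excluded_persons,
                "excluded_visits": report.excluded_visits,
                "excluded_series": report.excluded_series,
                "decisions": report.decisions,
            },
            default=str,
        )
    )
    meta.to_csv(out / "series_metadata.csv", index=False)

    # --- DFA
    dfa_params = DFAParams(**config.dfa) if config.dfa else DFAParams()
    dfa_rows = []
    for s in series:
        res = dfa_alpha(s.values, dfa_params, allow_short=config.allow_short_series)
        dfa_rows.append(
            {
                "person_id": s.person_id,
                "visit_id": s.visit_id,
                "movie_id": s.movie_id,
                "condition": s.condition,
                "segment_index": s.segment_index,
                "alpha": res.alpha,
                "r2": res.r2,
                "n": res.n_used,
                "noise_class": classify_noise(res.alpha),
                "scales": " ".join(map(str, res.scales.tolist())),
            }
        )
    dfa_table = pd.DataFrame(
        dfa_rows,
        columns=[
            "person_id",
            "visit_id",
            "movie_id",
            "condition",
            "segment_index",
            "alpha",
            "r2",
            "n",
            "noise_class",
            "scales",
        ],
    )
    dfa_table.to_csv(out / "dfa_results.csv", index=False)
    manifest["stages"]["dfa"] = {"series": len(dfa_table)}

    # --- AOI
    aoi_tables = face_looking(kept_segments, tracks, geometry, counterpart)
    for level, df in aoi_tables.items():
        df.to_csv(out / f"aoi_{level}.csv", index=False)
    manifest["stages"]["aoi"] = {
        "segments_tallied": int(len(aoi_tables["segment"]))
    }

    # --- models
    model_summary: dict = {"fitted": False}
    if config.fit_models and not dfa_table.empty:
        records = dfa_table.merge(
            meta,
            on=["person_id", "visit_id", "movie_id", "condition", "segment_index"],
            how="left",
        )
        seg_aoi = aoi_tables["segment"]
        if not seg_aoi.empty:
            records = records.merge(
                seg_aoi[
                    ["person_id", "visit_id", "movie_id", "segment_index", "proportion"]
                ].rename(columns={"proportion": "face_prop"}),
                on=["person_id", "visit_id", "movie_id", "segment_index"],
                how="left",
            )
        records["age_months"] = [
            ages.get((p, v), np.nan)
            for p, v in zip(records["person_id"], records["visit_id"])
        ]
        if records["age_months"].isna().all():
            records["age_months"] = 0.0
        enough = (
            records["person_id"].nunique() >= 2
            and records["visit_id"].nunique() >= 2
        )
        if enough:
            design = build_design(records)
            has_age = design["age_months"].nunique() > 1
            base_fixed = ("age_person_c", "age_visit_c") if has_age else ()
            cond_fixed = base_fixed + ("pixelated", "attention_cue")
            base = fit_alpha_model(
                design,
                AlphaModelSpec(fixed=base_fixed, random_person_age=has_age),
            )
            cond = fit_alpha_model(
                design,
                AlphaModelSpec(fixed=cond_fixed, random_person_age=has_age),
            )
            delta, ddf, p = lrt(base, cond)
            model_summary = {
                "fitted": True,
                "baseline": _model_dict(base),
                "condition_model": _model_dict(cond),
                "lrt_condition": {"delta_minus2LL": delta, "delta_df": ddf, "p": p},
                "variance_explained": variance_explained(cond, design["alpha"]),
            }
        else:
            model_summary = {
                "fitted": False,
                "reason": "not enough persons/visits after QC",
            }
    (out / "model_summary.json").write_text(json.dumps(model_summary, default=float))
    manifest["stages"]["models"] = {"fitted": model_summary.get("fitted", False)}

    (out / "manifest.json").write_text(json.dumps(manifest, default=str))
    return {
        "qc_report": report,
        "series_metadata": meta,
        "dfa_table": dfa_table,
        "aoi_tables": aoi_tables,
        "model_summary": model_summary,
        "manifest": manifest,
    }


def _model_dict(result) -> dict:
    return {
        "params": {k: float(v) for k, v in result.params.items()},
        "se": {k: float(v) for k, v in result.se.items()},
        "log_likelihood": result.llf,
        "aic": result.aic,
        "bic": result.bic,
        "random_var": result.random_var,
        "converged": result.converged,
        "n_obs": result.n_obs,
        "formula": result.formula,
    }
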