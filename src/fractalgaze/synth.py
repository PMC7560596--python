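"""Synthetic colored-noise series and multi-level eye-tracking datasets.

Three layers of generation, each with a known ground truth:

* :func:`generate_colored_noise` — 1/f^beta series by Fourier spectral
  synthesis: Gaussian white noise is given the exact target spectrum by
  scaling its Fourier amplitudes by f^(-beta/2).  Under the standard
  monofractal correspondence the DFA exponent of such a series is
  ``alpha = (beta + 1) / 2``.
* :func:`generate_gaze_session` — one lab visit: per-segment 300 Hz
  binocular gaze positions whose displacement-magnitude (D/T) dynamics
  follow a colored-noise series at a target alpha, plus blink gaps
  (< 200 ms, valid-flanked), longer dropout, per-eye Gaussian precision
  jitter, and a face-AOI track engineered so a controllable fraction of
  valid samples falls inside a face rectangle.
* :func:`generate_cohort` — a person -> visit -> movie -> segment table of
  realized scaling exponents built from injected fixed effects (age,
  condition, face-looking), nested random effects, and residual noise,
  for parameter-recovery experiments on the modeling stage.

The session generator shapes the magnitude series directly — the quantity
DFA consumes — and only then lays out 2-D positions with random step
directions (reflected at the screen edges), so the injected exponent lives
in the analyzed series by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .aoi import AoiTrack, FaceRect
from .errors import InvalidSpecError
from .models import center_multilevel
from .preprocess import GazeSegment, ScreenGeometry, Session


def beta_to_alpha(beta: float) -> float:
    """Monofractal correspondence between spectral and DFA exponents."""
    return (beta + 1.0) / 2.0


def alpha_to_beta(alpha: float) -> float:
    return 2.0 * alpha - 1.0


# ---------------------------------------------------------------------------
# colored noise


@dataclass(frozen=True)
class NoiseSpec:
    """A 1/f^beta noise request: length, spectral exponent, RNG seed."""

    n: int
    beta: float
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidSpecError("n must be >= 2")
        if not -1.0 <= self.beta <= 3.0:
            raise InvalidSpecError("beta must be within [-1, 3]")


def generate_colored_noise(spec: NoiseSpec) -> np.ndarray:
    """Series with power spectral density proportional to 1/f^beta.

    Spectral synthesis: complex Gaussian Fourier coefficients are scaled
    by f^(-beta/2) and inverse-transformed; the DC component is zero, so
    the output has (numerically) zero mean.  Output is standardized to
    unit sample variance; identical specs give bit-identical series.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.fft.rfftfreq(spec.n, d=1.0)
    coeff = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-spec.beta / 2.0)
    x = np.fft.irfft(coeff * amp, n=spec.n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


# ---------------------------------------------------------------------------
# session generation


@dataclass(frozen=True)
class MovieSpec:
    """One movie viewing: condition, id, and segment boundaries (ms).

    ``segment_boundaries_ms`` has k+1 strictly increasing entries for k
    segments, expressed in within-movie time.  Optional per-movie
    overrides of the session's target alpha and face-look probability.
    """

    movie_id: str
    condition: str
    segment_boundaries_ms: tuple[float, ...]
    target_alpha: float | None = None
    face_look_prob: float | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.segment_boundaries_ms, dtype=float)
        if b.size < 2 or np.any(np.diff(b) <= 0):
            raise InvalidSpecError("segment boundaries must be strictly increasing")


def default_movie_set() -> tuple[MovieSpec, ...]:
    """The stimulus battery of one visit.

    Four ~20 s social movies cut at movement events into 3-4 segments of
    roughly 5-8 s, their pixelated counterparts sharing the same cuts, and
    five ~6 s attention-cue presentations.
    """
    social_cuts = {
        "m1": (0.0, 7000.0, 14000.0, 20000.0),
        "m2": (0.0, 6500.0, 13500.0, 20000.0),
        "m3": (0.0, 7500.0, 14500.0, 20000.0),
        "m4": (0.0, 5000.0, 11000.0, 16000.0, 20000.0),
    }
    movies = [
        MovieSpec(movie_id=f"soc_{k}", condition="Social", segment_boundaries_ms=v)
        for k, v in social_cuts.items()
    ]
    movies += [
        MovieSpec(movie_id=f"pix_{k}", condition="Pixelated", segment_boundaries_ms=v)
        for k, v in social_cuts.items()
    ]
    movies += [
        MovieSpec(
            movie_id=f"cue_{i}",
            condition="AttentionCue",
            segment_boundaries_ms=(0.0, 6000.0),
        )
        for i in range(1, 6)
    ]
    return tuple(movies)


@dataclass(frozen=True)
class SessionSpec:
    """Everything needed to simulate one eye-tracking visit.

    Magnitude dynamics: the D/T series of each segment is an affine,
    clipped-at-zero transform of a colored-noise series at the segment's
    target alpha (``mag_mean_px`` +/- ``mag_sd_px`` pixels per sample
    interval); affine transforms leave the DFA exponent untouched and the
    clip is engaged for well under 1% of samples at the defaults.

    Noise model: blinks arrive as a Poisson process at
    ``blink_rate_per_min`` with durations uniform in
    ``blink_duration_ms_range`` (kept under the 200 ms blink cap and
    flanked by valid samples); ``dropout_fraction`` of samples is removed
    in longer (300-1000 ms) gaps; per-eye, per-axis Gaussian jitter of
    ``precision_jitter_deg`` emulates finite recording precision.
    """

    person_id: str = "p001"
    visit_id: str = "v1"
    visit_age_months: float = 12.0
    movies: tuple[MovieSpec, ...] = field(default_factory=default_movie_set)
    sampling_rate_hz: float = 300.0
    target_alpha: float = 1.0
    blink_rate_per_min: float = 8.0
    blink_duration_ms_range: tuple[float, float] = (60.0, 180.0)
    dropout_fraction: float = 0.05
    precision_jitter_deg: float = 0.02
    face_look_prob: float = 0.4
    mag_mean_px: float = 12.0
    mag_sd_px: float = 4.0
    frame_rate_hz: float = 30.0
    face_size_px: tuple[float, float] = (220.0, 260.0)
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise InvalidSpecError("sampling_rate_hz must be positive")
        if not 0.0 < self.target_alpha < 2.0:
            raise InvalidSpecError("target_alpha must be in (0, 2)")
        if self.blink_rate_per_min < 0:
            raise InvalidSpecError("blink_rate_per_min must be >= 0")
        lo, hi = self.blink_duration_ms_range
        if not 0 < lo <= hi:
            raise InvalidSpecError("blink duration range must satisfy 0 < lo <= hi")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise InvalidSpecError("dropout_fraction must be in [0, 1)")
        if self.precision_jitter_deg < 0:
            raise InvalidSpecError("precision_jitter_deg must be >= 0")
        if not 0.0 <= self.face_look_prob <= 1.0:
            raise InvalidSpecError("face_look_prob must be in [0, 1]")
        for m in self.movies:
            _ = m  # MovieSpec validates itself


def _place_gaps(
    n: int,
    dt_ms: float,
    rng: np.random.Generator,
    blink_rate_per_min: float,
    blink_dur_range: tuple[float, float],
    dropout_fraction: float,
) -> tuple[np.ndarray, list[tuple[int, int]], list[tuple[int, int]]]:
    """Mark invalid samples: blink runs (< 200 ms) and longer dropout runs.

    Gaps never touch the segment edges and are separated by at least one
    valid sample, so every blink is flanked by valid data.
    """
    valid = np.ones(n, dtype=bool)
    blinks: list[tuple[int, int]] = []
    dropouts: list[tuple[int, int]] = []

    def try_place(start: int, length: int, out: list[tuple[int, int]]) -> None:
        end = start + length - 1
        if start < 1 or end > n - 2:
            return
        lo = max(start - 1, 0)
        hi = min(end + 2, n)
        if not valid[lo:hi].all():  # keep gaps separated by valid samples
            return
        valid[start : end + 1] = False
        out.append((start, end))

    if dropout_fraction > 0:
        target = int(round(dropout_fraction * n))
        guard = 0
        while (~valid).sum() < target and guard < 200:
            guard += 1
            dur_ms = rng.uniform(300.0, 1000.0)
            length = max(int(round(dur_ms / dt_ms)), int(np.ceil(201.0 / dt_ms)))
            start = int(rng.integers(1, max(n - length - 1, 2)))
            try_place(start, length, dropouts)

    if blink_rate_per_min > 0:
        duration_min = n * dt_ms / 60000.0
        n_blinks = rng.poisson(blink_rate_per_min * duration_min)
        for _ in range(n_blinks):
            dur_ms = rng.uniform(*blink_dur_range)
            # spanned duration from flank to flank is (length + 1) * dt
            length = max(int(round(dur_ms / dt_ms)), 1)
            if (length + 1) * dt_ms >= 200.0:
                length = int(np.floor(200.0 / dt_ms)) - 2
            start = int(rng.integers(1, max(n - length - 1, 2)))
            try_place(start, length, blinks)

    return valid, blinks, dropouts


def _segment_positions(
    mags: np.ndarray,
    rng: np.random.Generator,
    screen: ScreenGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-direction walk with given step magnitudes, reflected at edges."""
    n = mags.size + 1
    theta = rng.uniform(0.0, 2.0 * np.pi, size=mags.size)
    steps_x = mags * np.cos(theta)
    steps_y = mags * np.sin(theta)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = screen.width_px / 2.0, screen.height_px / 2.0
    np.cumsum(steps_x, out=x[1:])
    x[1:] += x[0]
    np.cumsum(steps_y, out=y[1:])
    y[1:] += y[0]
    x = _reflect(x, 0.0, screen.width_px - 1.0)
    y = _reflect(y, 0.0, screen.height_px - 1.0)
    return x, y


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a trajectory into [lo, hi] by mirror reflection."""
    span = hi - lo
    v = np.mod(v - lo, 2.0 * span)
    v = np.where(v > span, 2.0 * span - v, v)
    return v + lo


def _face_track_for_segment(
    t_ms: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    p_face: float,
    rng: np.random.Generator,
    screen: ScreenGeometry,
    frame_rate_hz: float,
    face_size: tuple[float, float],
) -> dict[int, list[FaceRect]]:
    """Per-frame face rectangles that contain the gaze on ~p_face of frames.

    For each movie frame, a Bernoulli(p_face) draw decides whether the
    (moving) face rectangle is centered on that frame's gaze samples —
    covering them all — or displaced to the far side of the screen where
    it contains none.  Gaze moves little within one 33 ms frame, so the
    realized sample-level face-look fraction tracks p_face closely.
    """
    w, h = face_size
    frames: dict[int, list[FaceRect]] = {}
    idx = np.floor(t_ms / 1000.0 * frame_rate_hz).astype(int)
    for f in np.unique(idx):
        in_frame = (idx == f) & valid
        if not in_frame.any():
            # no valid gaze this frame: park the face at screen center
            cx, cy = screen.width_px / 2.0, screen.height_px / 2.0
            look = False
        else:
            cx = float(np.mean([x[in_frame].min(), x[in_frame].max()]))
            cy = float(np.mean([y[in_frame].min(), y[in_frame].max()]))
            look = bool(rng.random() < p_face)
        if look:
            # cover the frame's samples; clamp the center so the rect stays
            # on-screen (sample spread per frame is far below the rect size)
            cx = float(np.clip(cx, w / 2.0, screen.width_px - w / 2.0))
            cy = float(np.clip(cy, h / 2.0, screen.height_px - h / 2.0))
        else:
            # far corner from the gaze: never contains this frame's samples
            cx = screen.width_px - w if cx < screen.width_px / 2.0 else w / 2.0
            cy = screen.height_px - h if cy < screen.height_px / 2.0 else h / 2.0
        frames[int(f)] = [
            FaceRect(
                face_id="face1",
                x_min=cx - w / 2.0,
                y_min=cy - h / 2.0,
                x_max=cx + w / 2.0,
                y_max=cy + h / 2.0,
            )
        ]
    return frames


def generate_gaze_session(
    spec: SessionSpec,
) -> tuple[Session, dict, dict[str, AoiTrack]]:
    """Simulate one visit: segments, ground truth, and face-AOI tracks.

    Returns ``(session, ground_truth, tracks)``.  ``ground_truth`` records
    every injected parameter per segment (target alpha, spectral beta,
    blink and dropout runs, face-look probability).  ``tracks`` maps each
    Social/Pixelated movie id to its generated AOI track; attention-cue
    movies have no faces and get no track.
    """
    rng = np.random.default_rng(spec.seed)
    dt_ms = 1000.0 / spec.sampling_rate_hz
    jitter_px = (
        spec.precision_jitter_deg / spec.screen.width_deg * spec.screen.width_px
    )
    segments: list[GazeSegment] = []
    tracks: dict[str, AoiTrack] = {}
    truth: dict = {
        "person_id": spec.person_id,
        "visit_id": spec.visit_id,
        "visit_age_months": spec.visit_age_months,
        "params": {
            "sampling_rate_hz": spec.sampling_rate_hz,
            "blink_rate_per_min": spec.blink_rate_per_min,
            "blink_duration_ms_range": list(spec.blink_duration_ms_range),
            "dropout_fraction": spec.dropout_fraction,
            "precision_jitter_deg": spec.precision_jitter_deg,
            "mag_mean_px": spec.mag_mean_px,
            "mag_sd_px": spec.mag_sd_px,
        },
        "segments": [],
    }

    for movie in spec.movies:
        bounds = np.asarray(movie.segment_boundaries_ms, dtype=float)
        alpha = movie.target_alpha if movie.target_alpha is not None else spec.target_alpha
        p_face = (
            movie.face_look_prob
            if movie.face_look_prob is not None
            else spec.face_look_prob
        )
        movie_frames: dict[int, list[FaceRect]] = {}
        for si in range(bounds.size - 1):
            start_ms, end_ms = bounds[si], bounds[si + 1]
            n = int(round((end_ms - start_ms) / dt_ms))
            if n < 2:
                raise InvalidSpecError(
                    f"segment {si} of movie {movie.movie_id} too short"
                )
            t_ms = start_ms + np.arange(n) * dt_ms
            noise = generate_colored_noise(
                NoiseSpec(
                    n=max(n - 1, 2),
                    beta=alpha_to_beta(alpha),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            mags = np.clip(spec.mag_mean_px + spec.mag_sd_px * noise, 0.0, None)
            x, y = _segment_positions(mags, rng, spec.screen)
            valid, blinks, dropouts = _place_gaps(
                n,
                dt_ms,
                rng,
                spec.blink_rate_per_min,
                spec.blink_duration_ms_range,
                spec.dropout_fraction,
            )
            if movie.condition != "AttentionCue":
                movie_frames.update(
                    _face_track_for_segment(
                        t_ms,
                        x,
                        y,
                        valid,
                        p_face,
                        rng,
                        spec.screen,
                        spec.frame_rate_hz,
                        spec.face_size_px,
                    )
                )
            lx = x + rng.standard_normal(n) * jitter_px
            ly = y + rng.standard_normal(n) * jitter_px
            rx = x + rng.standard_normal(n) * jitter_px
            ry = y + rng.standard_normal(n) * jitter_px
            for arr in (lx, ly, rx, ry):
                arr[~valid] = np.nan
            segments.append(
                GazeSegment(
                    t_ms=t_ms,
                    left_x=lx,
                    left_y=ly,
                    right_x=rx,
                    right_y=ry,
                    left_valid=valid.copy(),
                    right_valid=valid.copy(),
                    person_id=spec.person_id,
                    visit_id=spec.visit_id,
                    movie_id=movie.movie_id,
                    condition=movie.condition,
                    segment_index=si,
                    nominal_rate_hz=spec.sampling_rate_hz,
                )
            )
            truth["segments"].append(
                {
                    "movie_id": movie.movie_id,
                    "condition": movie.condition,
                    "segment_index": si,
                    "target_alpha": alpha,
                    "beta": alpha_to_beta(alpha),
                    "n_samples": n,
                    "face_look_prob": p_face if movie.condition != "AttentionCue" else None,
                    "blinks": blinks,
                    "dropouts": dropouts,
                }
            )
        if movie.condition != "AttentionCue":
            tracks[movie.movie_id] = AoiTrack(
                frames=movie_frames,
                frame_rate_hz=spec.frame_rate_hz,
                movie_id=movie.movie_id,
            )

    session = Session(
        person_id=spec.person_id,
        visit_id=spec.visit_id,
        segments=segments,
        age_months=spec.visit_age_months,
    )
    return session, truth, tracks


# ---------------------------------------------------------------------------
# cohort generation


def _default_fixed_effects() -> dict[str, float]:
    return {
        "intercept": 0.85,
        "age": 0.001,
        "pixelated": -0.023,
        "attention_cue": -0.030,
        "age_x_pixelated": 0.0,
        "age_x_attention_cue": 0.0,
    }


def _default_random_sd() -> dict[str, float]:
    return {
        "person_intercept": float(np.sqrt(0.001)),
        "person_age": 0.0005,
        "visit_intercept": float(np.sqrt(0.0015)),
        "movie_intercept": 0.005,
    }


def _default_face_logit() -> dict[str, float]:
    return {
        "intercept": -0.5,
        "age": 0.02,
        "pixelated": -1.71,
        "age_x_pixelated": 0.0,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a multi-visit infant cohort.

    The scaling exponent of each retained segment is::

        alpha = intercept + age * (age_m - age_center)
              + pixelated/attention_cue offsets (+ age-interaction terms)
              + face-looking effects on the four centered face terms
              + person intercept + person age slope + visit + movie effects
              + residual,   clipped to (0, 2)

    Face-looking counts are drawn from a binomial whose logit-probability
    carries its own fixed effects and a person-level random intercept;
    the alpha face effects act on the multi-level *centered* observed
    proportions, matching how the modeling stage decomposes them.
    Variances mirror the observational estimates: residual 0.008,
    visit-intercept ~0.0015, near-zero person and movie variance.
    """

    n_persons: int = 190
    visits_range: tuple[int, int] = (1, 3)
    age_range_months: tuple[float, float] = (3.0, 35.0)
    age_center_months: float = 15.0
    true_fixed_effects: dict = field(default_factory=_default_fixed_effects)
    face_effects: dict = field(
        default_factory=lambda: {"person": 0.0, "visit": 0.0, "movie": 0.0, "segment": 0.0}
    )
    face_logit_effects: dict = field(default_factory=_default_face_logit)
    face_person_sd: float = 0.5
    random_sd: dict = field(default_factory=_default_random_sd)
    residual_sd: float = float(np.sqrt(0.008))
    segment_retention: float = 0.7
    n_valid_range: tuple[int, int] = (1000, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise InvalidSpecError("n_persons must be >= 1")
        if any(sd < 0 for sd in self.random_sd.values()) or self.residual_sd < 0:
            raise InvalidSpecError("all standard deviations must be >= 0")
        if not 0 < self.segment_retention <= 1:
            raise InvalidSpecError("segment_retention must be in (0, 1]")


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, list[SessionSpec]]:
    """Draw a cohort table of segment-level records plus session specs.

    The table holds everything the modeling stage consumes (ids, age,
    condition, realized alpha, face counts) together with the latent truth
    (fixed-effect predictor, sampled random effects).  The session specs
    let any subset of the cohort be expanded into full raw gaze recordings
    with matching target alphas.
    """
    rng = np.random.default_rng(spec.seed)
    fe = {**_default_fixed_effects(), **spec.true_fixed_effects}
    rsd = {**_default_random_sd(), **spec.random_sd}
    flog = {**_default_face_logit(), **spec.face_logit_effects}
    lo_age, hi_age = spec.age_range_months
    movies = default_movie_set()

    rows: list[dict] = []
    session_specs: list[SessionSpec] = []
    for pi in range(spec.n_persons):
        person_id = f"p{pi + 1:04d}"
        person_int = rng.normal(0.0, rsd["person_intercept"])
        person_slope = rng.normal(0.0, rsd["person_age"])
        face_person = rng.normal(0.0, spec.face_person_sd)
        n_visits = int(rng.integers(spec.visits_range[0], spec.visits_range[1] + 1))
        ages = np.sort(rng.uniform(lo_age, hi_age, size=n_visits))
        for vi in range(n_visits):
            visit_id = f"{person_id}_v{vi + 1}"
            visit_int = rng.normal(0.0, rsd["visit_intercept"])
            age_c = ages[vi] - spec.age_center_months
            visit_rows: list[dict] = []
            for movie in movies:
                movie_int = rng.normal(0.0, rsd["movie_intercept"])
                n_segments = len(movie.segment_boundaries_ms) - 1
                pix = 1.0 if movie.condition == "Pixelated" else 0.0
                cue = 1.0 if movie.condition == "AttentionCue" else 0.0
                for si in range(n_segments):
                    if rng.random() > spec.segment_retention:
                        continue
                    predictor = (
                        fe["intercept"]
                        + fe["age"] * age_c
                        + fe["pixelated"] * pix
                        + fe["attention_cue"] * cue
                        + fe["age_x_pixelated"] * age_c * pix
                        + fe["age_x_attention_cue"] * age_c * cue
                    )
                    n_valid = int(rng.integers(*spec.n_valid_range))
                    if cue:
                        n_face = np.nan
                        n_nonface = np.nan
                    else:
                        logit = (
                            flog["intercept"]
                            + flog["age"] * age_c
                            + flog["pixelated"] * pix
                            + flog["age_x_pixelated"] * age_c * pix
                            + face_person
                        )
                        p = 1.0 / (1.0 + np.exp(-logit))
                        n_face = int(rng.binomial(n_valid, p))
                        n_nonface = n_valid - n_face
                    visit_rows.append(
                        {
                            "person_id": person_id,
                            "visit_id": visit_id,
                            "movie_id": movie.movie_id,
                            "condition": movie.condition,
                            "segment_index": si,
                            "age_months": ages[vi],
                            "n_valid": n_valid,
                            "n_face": n_face,
                            "n_nonface": n_nonface,
                            "true_predictor": predictor,
                            "true_person_intercept": person_int,
                            "true_person_slope": person_slope,
                            "true_visit_intercept": visit_int,
                            "true_movie_intercept": movie_int,
                            "resid": rng.normal(0.0, spec.residual_sd),
                        }
                    )
            rows.extend(visit_rows)
            session_specs.append(
                SessionSpec(
                    person_id=person_id,
                    visit_id=visit_id,
                    visit_age_months=float(ages[vi]),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )

    table = pd.DataFrame(rows)
    if table.empty:
        raise InvalidSpecError("cohort spec produced no segments")
    table["face_prop"] = table["n_face"] / table["n_valid"]

    # face-looking effects act on the centered observed proportions so the
    # generative model matches the modeling stage's decomposition exactly
    sp = table["condition"] != "AttentionCue"
    face_terms = center_multilevel(table.loc[sp], "face_prop", name="face")
    face_contrib = pd.Series(0.0, index=table.index)
    for level in ("person", "visit", "movie", "segment"):
        coef = spec.face_effects.get(level, 0.0)
        if coef:
            face_contrib.loc[sp] += coef * face_terms[f"face_{level}_c"]

    alpha = (
        table["true_predictor"]
        + table["true_person_intercept"]
        + table["true_person_slope"] * (table["age_months"] - spec.age_center_months)
        + table["true_visit_intercept"]
        + table["true_movie_intercept"]
        + face_contrib
        + table["resid"]
    )
    table["alpha"] = np.clip(alpha, 1e-6, 2.0 - 1e-6)

    # sessions carry the segment's realized alpha as target where retained
    session_specs = _attach_session_alphas(session_specs, table)
    return table, session_specs


def _attach_session_alphas(
    session_specs: list[SessionSpec], table: pd.DataFrame
) -> list[SessionSpec]:
    """Give each session spec per-movie target alphas from the cohort table."""
    by_visit = table.groupby("visit_id")
    out = []
    for ss in session_specs:
        if ss.visit_id not in by_visit.groups:
            out.append(ss)
            continue
        sub = by_visit.get_group(ss.visit_id)
        movie_alpha = sub.groupby("movie_id")["alpha"].mean()
        movies = tuple(
            replace(m, target_alpha=float(np.clip(movie_alpha.get(m.movie_id, 1.0), 0.05, 1.95)))
            for m in ss.movies
        )
        out.append(replace(ss, movies=movies))
    return out
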