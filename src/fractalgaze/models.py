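"""Multi-level models of gaze fractality and face-looking.

The observational design is 4-level nested: segments within movies within
lab visits within persons.  Covariates are decomposed by multi-level
centering — person means centered at the grand mean, visit means at the
person mean, movie means at the visit mean, segment values at the movie
mean — so each coefficient isolates variation at one level.

Linear mixed models (scaling exponent alpha as outcome) are fit by maximum
likelihood with statsmodels' MixedLM: random person intercept and age
slope, plus visit- and movie-level intercept variance components.  ML (not
REML) is the default because inference rests on likelihood-ratio tests of
fixed effects.  The binomial face-looking model (counts of samples in face
vs non-face regions, logit link, person-level random effects) is fit with
lme4's ``glmer`` through an Rscript subprocess — the reference
implementation for frequentist GLMMs.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidComparisonError, InvalidInputError

ID_COLS = ("person_id", "visit_id", "movie_id")

#: canonical short names for centered covariates
_BASENAMES = {
    "age_months": "age",
    "face_prop": "face",
    "precision_deg": "precision",
    "proportion_interpolated": "interp",
    "longest_run_length": "runlen",
}


# ---------------------------------------------------------------------------
# design construction


def center_multilevel(
    df: pd.DataFrame,
    col: str,
    name: str | None = None,
    levels: Sequence[str] = ("person", "visit", "movie", "segment"),
) -> pd.DataFrame:
    """Decompose a covariate into between/within components by centering.

    Returns a DataFrame (aligned to ``df``) with up to four columns:
    ``{name}_person_c`` (person mean - grand mean), ``{name}_visit_c``
    (visit mean - person mean), ``{name}_movie_c`` (movie mean - visit
    mean), and ``{name}_segment_c`` (value - movie mean).  NaN values are
    ignored in all means.
    """
    for c in ID_COLS:
        if c not in df.columns:
            raise InvalidInputError(f"missing nesting id column {c!r}")
    name = name or _BASENAMES.get(col, col)
    x = df[col].astype(float)
    grand = x.mean()
    person_avg = x.groupby(df["person_id"]).transform("mean")
    visit_avg = x.groupby([df["person_id"], df["visit_id"]]).transform("mean")
    movie_avg = x.groupby(
        [df["person_id"], df["visit_id"], df["movie_id"]]
    ).transform("mean")
    out = {}
    if "person" in levels:
        out[f"{name}_person_c"] = person_avg - grand
    if "visit" in levels:
        out[f"{name}_visit_c"] = visit_avg - person_avg
    if "movie" in levels:
        out[f"{name}_movie_c"] = movie_avg - visit_avg
    if "segment" in levels:
        out[f"{name}_segment_c"] = x - movie_avg
    return pd.DataFrame(out, index=df.index)


DEFAULT_CENTERING: dict[str, tuple[str, ...]] = {
    "age_months": ("person", "visit"),
    "precision_deg": ("person", "visit"),
    "proportion_interpolated": ("person", "visit", "movie", "segment"),
    "longest_run_length": ("person", "visit", "movie", "segment"),
    "face_prop": ("person", "visit", "movie", "segment"),
}


def build_design(
    records: pd.DataFrame,
    centering_plan: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Segment-level records -> model-ready design table.

    Adds condition dummies (``pixelated``, ``attention_cue``; Social is the
    omitted reference), all centered covariates present in the input per
    the centering plan, a total centered age (for random-slope use), and a
    globally unique movie identifier ``movie_uid`` for nested variance
    components.
    """
    for c in ID_COLS:
        if c not in records.columns:
            raise InvalidInputError(f"missing nesting id column {c!r}")
    if "condition" not in records.columns:
        raise InvalidInputError("missing 'condition' column")
    plan = centering_plan or DEFAULT_CENTERING
    design = records.copy()
    design["pixelated"] = (design["condition"] == "Pixelated").astype(float)
    design["attention_cue"] = (design["condition"] == "AttentionCue").astype(float)
    design["movie_uid"] = (
        design["person_id"].astype(str)
        + "/"
        + design["visit_id"].astype(str)
        + "/"
        + design["movie_id"].astype(str)
    )
    for col, levels in plan.items():
        if col in design.columns:
            centered = center_multilevel(design, col, levels=levels)
            design[centered.columns] = centered
    if {"age_person_c", "age_visit_c"}.issubset(design.columns):
        design["age_total_c"] = design["age_person_c"] + design["age_visit_c"]
    return design


# ---------------------------------------------------------------------------
# results container


@dataclass
class ModelResult:
    """Estimates and fit indices of one mixed-model fit."""

    params: pd.Series
    se: pd.Series
    llf: float
    df_params: int
    n_obs: int
    fitted: np.ndarray
    random_var: dict[str, float]
    converged: bool
    method: str
    formula: str
    backend: str
    fixed_terms: tuple[str, ...] = ()

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.df_params * np.log(self.n_obs)

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for a fixed effect."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        est, se = self.params[name], self.se[name]
        return est - z * se, est + z * se


# ---------------------------------------------------------------------------
# linear mixed models (statsmodels backend)


@dataclass(frozen=True)
class AlphaModelSpec:
    """Specification for an alpha linear mixed model.

    ``fixed`` are design-column names (an intercept is always included);
    ``interactions`` are pairs of column names whose product is added.
    Random structure: person intercept (always), optional person age
    slope, and visit/movie intercept variance components; the visit-level
    Pixelated random slope mirrors the face-looking analysis.
    """

    fixed: tuple[str, ...] = (
        "age_person_c",
        "age_visit_c",
        "pixelated",
        "attention_cue",
    )
    interactions: tuple[tuple[str, str], ...] = ()
    random_person_age: bool = True
    random_visit_intercept: bool = True
    random_movie_intercept: bool = True
    random_visit_pixelated: bool = False
    reml: bool = False


def _prepare_model_frame(
    design: pd.DataFrame, spec: AlphaModelSpec, outcome: str
) -> tuple[pd.DataFrame, list[str]]:
    """Materialize interaction columns and validate the model frame."""
    df = design.copy()
    terms = list(spec.fixed)
    for a, b in spec.interactions:
        col = f"{a}_x_{b}"
        df[col] = df[a] * df[b]
        terms.append(col)
    needed = terms + [outcome, "person_id", "visit_id", "movie_uid"]
    for t in needed:
        if t not in df.columns:
            raise InvalidInputError(f"design lacks column {t!r}")
    if spec.random_person_age and "age_total_c" not in df.columns:
        raise InvalidInputError("design lacks 'age_total_c' for the random age slope")
    if df[terms + [outcome]].isna().any().any():
        raise InvalidInputError("design contains missing values in model columns")
    for c in ("person_id", "visit_id", "movie_uid"):
        if df[c].nunique() < 2:
            raise InvalidInputError(f"need >= 2 units at level {c}")
    return df, terms


def fit_alpha_model(
    design: pd.DataFrame,
    spec: AlphaModelSpec | None = None,
    outcome: str = "alpha",
    backend: str = "statsmodels",
) -> ModelResult:
    """Fit a linear mixed model for the scaling exponent by ML.

    ``backend="statsmodels"`` uses MixedLM with a Powell warm start
    followed by L-BFGS polish (the near-boundary variance components in
    data of this shape defeat a cold gradient start);
    ``backend="lme4"`` delegates to lmer through Rscript, which is
    several-fold faster and is used for replicate studies.  Both are
    maximum likelihood unless ``spec.reml`` is set.  Non-convergence or a
    singular fit is reported through the ``converged`` flag, never
    silently repaired.
    """
    spec = spec or AlphaModelSpec()
    if backend == "lme4":
        return fit_alpha_models_batch(design, spec, outcome=outcome)[0]
    import statsmodels.formula.api as smf

    df, terms = _prepare_model_frame(design, spec, outcome)
    formula = f"{outcome} ~ " + " + ".join(terms) if terms else f"{outcome} ~ 1"
    re_formula = "~age_total_c" if spec.random_person_age else "~1"
    vc: dict[str, str] = {}
    if spec.random_visit_intercept:
        vc["visit"] = "0 + C(visit_id)"
    if spec.random_movie_intercept:
        vc["movie"] = "0 + C(movie_uid)"
    if spec.random_visit_pixelated:
        vc["visit_pix"] = "0 + C(visit_id):pixelated"

    model = smf.mixedlm(
        formula,
        data=df,
        groups=df["person_id"],
        re_formula=re_formula,
        vc_formula=vc or None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=spec.reml, method=["powell", "lbfgs"], maxiter=1000)
        bse_fe = result.bse_fe  # may warn on a near-singular information matrix

    q = result.cov_re.shape[0]
    k_var = q * (q + 1) // 2 + len(vc) + 1  # RE covariance + VCs + residual
    k = len(result.fe_params) + k_var
    random_var = {
        f"person_{n}": float(result.cov_re.iloc[i, i])
        for i, n in enumerate(result.cov_re.index)
    }
    if vc:
        for i, name in enumerate(model.exog_vc.names):
            random_var[name] = float(result.vcomp[i])
    random_var["residual"] = float(result.scale)
    return ModelResult(
        params=result.fe_params,
        se=bse_fe,
        llf=float(result.llf),
        df_params=k,
        n_obs=int(result.nobs),
        fitted=np.asarray(result.fittedvalues, dtype=float),
        random_var=random_var,
        converged=bool(result.converged),
        method="REML" if spec.reml else "ML",
        formula=formula + f" | re={re_formula}, vc={sorted(vc)}",
        backend="statsmodels-mixedlm",
        fixed_terms=tuple(["Intercept"] + terms),
    )


def _lmer_formula(spec: AlphaModelSpec, terms: Sequence[str], outcome: str) -> str:
    fixed = " + ".join(terms) or "1"
    re_parts = []
    re_parts.append(
        "(1 + age_total_c | person_id)" if spec.random_person_age else "(1 | person_id)"
    )
    if spec.random_visit_intercept and spec.random_visit_pixelated:
        re_parts.append("(1 + pixelated | visit_id)")
    elif spec.random_visit_intercept:
        re_parts.append("(1 | visit_id)")
    elif spec.random_visit_pixelated:
        re_parts.append("(0 + pixelated | visit_id)")
    if spec.random_movie_intercept:
        re_parts.append("(1 | movie_uid)")
    return f"{outcome} ~ {fixed} + " + " + ".join(re_parts)


def fit_alpha_models_batch(
    design: pd.DataFrame,
    spec: AlphaModelSpec | None = None,
    replicate_col: str | None = None,
    outcome: str = "alpha",
) -> list[ModelResult]:
    """Fit the alpha linear mixed model with lme4, one fit per replicate.

    All replicates run inside a single R session.  A boundary (singular)
    variance estimate is a valid maximum-likelihood solution and is not
    treated as non-convergence.
    """
    spec = spec or AlphaModelSpec()
    df, terms = _prepare_model_frame(design, spec, outcome)
    formula = _lmer_formula(spec, terms, outcome)
    fitcall = f"lmer({formula}, data = dd, REML = {'TRUE' if spec.reml else 'FALSE'})"
    keep = list(
        dict.fromkeys(
            terms
            + [outcome, "person_id", "visit_id", "movie_uid", "age_total_c", "pixelated"]
        )
    )
    keep = [c for c in keep if c in df.columns]
    recs = _run_lme4(df, keep, fitcall, replicate_col)
    return [
        _parse_lme4(rec, formula, method="REML" if spec.reml else "ML", terms=terms)
        for rec in recs
    ]


def fit_face_alpha_model(
    design: pd.DataFrame,
    spec: AlphaModelSpec | None = None,
) -> ModelResult:
    """Alpha regressed on multi-level face-looking, Social/Pixelated rows only.

    Fixed effects: the four centered face-looking terms, age (person and
    visit decomposition), and the Pixelated dummy; random structure:
    person intercept + age slope, visit intercept + Pixelated slope, movie
    intercept.  Attention-cue rows are rejected — there is no face AOI to
    look at in those trials.
    """
    if (design["condition"] == "AttentionCue").any():
        raise InvalidInputError(
            "face-looking models accept Social/Pixelated rows only"
        )
    spec = spec or AlphaModelSpec(
        fixed=(
            "face_person_c",
            "face_visit_c",
            "face_movie_c",
            "face_segment_c",
            "age_person_c",
            "age_visit_c",
            "pixelated",
        ),
        random_visit_pixelated=True,
    )
    return fit_alpha_model(design, spec)


# ---------------------------------------------------------------------------
# model comparison


def lrt(nested: ModelResult, full: ModelResult) -> tuple[float, int, float]:
    """Chi-square likelihood-ratio test of two nested ML fits.

    Returns ``(delta_minus2LL, delta_df, p)``.  Comparing a model with
    itself gives ``(0, 0, 1)`` by convention.
    """
    if nested.n_obs != full.n_obs:
        raise InvalidComparisonError(
            f"models fit on different row counts ({nested.n_obs} vs {full.n_obs})"
        )
    if nested.method != "ML" or full.method != "ML":
        raise InvalidComparisonError("LRT requires ML (not REML) fits")
    if nested.fixed_terms and full.fixed_terms and not set(
        nested.fixed_terms
    ).issubset(full.fixed_terms):
        raise InvalidComparisonError("fixed-effect sets are not nested")
    delta_df = full.df_params - nested.df_params
    if delta_df < 0:
        raise InvalidComparisonError("'full' model has fewer parameters than 'nested'")
    delta = 2.0 * (full.llf - nested.llf)
    if delta_df == 0:
        return float(delta), 0, 1.0
    p = float(stats.chi2.sf(max(delta, 0.0), delta_df))
    return float(delta), int(delta_df), p


def variance_explained(result: ModelResult, observed: Sequence[float]) -> float:
    """Proportion of variance explained: squared corr(fitted, observed)."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(result.fitted, dtype=float)
    if fit.size != obs.size:
        raise InvalidInputError("fitted and observed lengths differ")
    if np.ptp(fit) == 0 or np.ptp(obs) == 0:
        warnings.warn("constant fitted or observed values; variance explained is 0")
        return 0.0
    r = np.corrcoef(fit, obs)[0, 1]
    return float(r**2)


# ---------------------------------------------------------------------------
# binomial face-looking model (lme4 backend)


@dataclass(frozen=True)
class FaceModelSpec:
    """Specification for the binomial-logit face-looking GLMM.

    ``random="intercept"`` fits a person-level random intercept;
    ``random="full"`` additionally gives age and condition random slopes
    at the person level (the structure used for the observational data;
    random effects above the person level are deliberately not offered —
    richer structures failed to converge on data of this shape).
    """

    fixed: tuple[str, ...] = ("age_c", "pixelated", "age_c:pixelated")
    random: str = "full"
    covariates: tuple[str, ...] = ()


_R_TEMPLATE = """
suppressMessages({{library(lme4); library(jsonlite)}})
d <- read.csv("{csv}")
fit_one <- function(dd) {{
  m <- suppressWarnings(suppressMessages({fitcall}))
  co <- summary(m)$coefficients
  vc <- as.data.frame(VarCorr(m))
  vc <- vc[is.na(vc$var2), ]
  msgs <- m@optinfo$conv$lme4$messages
  list(
    names = rownames(co),
    estimate = unname(co[, 1]),
    se = unname(co[, 2]),
    loglik = as.numeric(logLik(m)),
    df = attr(logLik(m), "df"),
    n = nrow(dd),
    converged = is.null(msgs) || !any(grepl("failed to converge", msgs)),
    singular = isSingular(m),
    vc_names = paste(vc$grp, ifelse(is.na(vc$var1), "", vc$var1)),
    vc_vcov = vc$vcov
  )
}}
out <- lapply(split(d, d$X_replicate), fit_one)
cat(toJSON(out, auto_unbox = TRUE, digits = 12), file = "{out}")
"""


def _run_lme4(
    df: pd.DataFrame,
    columns: Sequence[str],
    fitcall: str,
    replicate_col: str | None,
) -> list[dict]:
    """Run one lme4 fit per replicate inside a single R session."""
    work = df[list(columns)].copy()
    work["X_replicate"] = df[replicate_col] if replicate_col else 0
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "data.csv"
        out = Path(tmp) / "fits.json"
        work.to_csv(csv, index=False)
        script = Path(tmp) / "fit.R"
        script.write_text(_R_TEMPLATE.format(csv=csv, fitcall=fitcall, out=out))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not out.exists():
            raise RuntimeError(f"lme4 backend failed:\n{proc.stderr[-2000:]}")
        payload = json.loads(out.read_text())
    return list(payload.values()) if isinstance(payload, dict) else payload


def _as_list(v) -> list:
    return v if isinstance(v, list) else [v]


def _parse_lme4(
    rec: dict, formula: str, method: str, terms: Sequence[str]
) -> ModelResult:
    names = [
        "Intercept" if n == "(Intercept)" else n for n in _as_list(rec["names"])
    ]
    est = np.asarray(_as_list(rec["estimate"]), dtype=float)
    se = np.asarray(_as_list(rec["se"]), dtype=float)
    random_var = {
        str(n).strip().replace(" ", "_"): float(v)
        for n, v in zip(_as_list(rec.get("vc_names", [])), _as_list(rec.get("vc_vcov", [])))
    }
    return ModelResult(
        params=pd.Series(est, index=names),
        se=pd.Series(se, index=names),
        llf=float(rec["loglik"]),
        df_params=int(rec["df"]),
        n_obs=int(rec["n"]),
        fitted=np.empty(0),
        random_var=random_var,
        converged=bool(rec["converged"]),
        method=method,
        formula=formula,
        backend="lme4",
        fixed_terms=tuple(["Intercept"] + [t for t in terms]),
    )


def _glmer_formula(spec: FaceModelSpec) -> str:
    fixed = " + ".join(spec.fixed + spec.covariates) or "1"
    if spec.random == "full":
        re = "(1 + age_c + pixelated | person_id)"
    else:
        re = "(1 | person_id)"
    return f"cbind(n_face, n_nonface) ~ {fixed} + {re}"


def fit_face_models_batch(
    data: pd.DataFrame,
    spec: FaceModelSpec | None = None,
    replicate_col: str | None = None,
) -> list[ModelResult]:
    """Fit the binomial face-looking GLMM, optionally once per replicate.

    ``data`` needs columns ``n_face``, ``n_nonface``, ``person_id``, and
    every fixed-effect column.  All replicates are fit inside a single R
    session to amortize interpreter startup.
    """
    spec = spec or FaceModelSpec()
    needed = {"n_face", "n_nonface", "person_id"} | {
        c for term in spec.fixed + spec.covariates for c in term.split(":")
    }
    missing = needed - set(data.columns)
    if missing:
        raise InvalidInputError(f"data lacks columns {sorted(missing)}")
    if (data["n_face"] + data["n_nonface"]).min() <= 0:
        raise InvalidInputError("each row needs at least one tallied sample")
    if data["n_face"].sum() == 0 or data["n_nonface"].sum() == 0:
        warnings.warn("all-zero or all-one outcomes: possible separation")

    formula = _glmer_formula(spec)
    fitcall = f"glmer({formula}, data = dd, family = binomial)"
    terms = list(spec.fixed + spec.covariates)
    keep = list(
        dict.fromkeys(
            ["n_face", "n_nonface", "person_id"]
            + [c for term in terms for c in term.split(":")]
        )
    )
    recs = _run_lme4(data, keep, fitcall, replicate_col)
    return [_parse_lme4(rec, formula, method="ML", terms=terms) for rec in recs]


def fit_face_model(
    data: pd.DataFrame, spec: FaceModelSpec | None = None
) -> ModelResult:
    """Binomial-logit mixed model of face vs non-face sample counts.

    Outcome: per-segment ``(n_face, n_nonface)`` count pairs; link:
    logit; random effects at the person level only.
    """
    return fit_face_models_batch(data, spec)[0]
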