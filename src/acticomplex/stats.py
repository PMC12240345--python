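"""Group-level statistics over the per-subject feature table.

The feature table has one row per subject: group (healthy = 1,
patient = 0 for modelling), age, sex, the traditional measures (avg,
cov, ac1, plus sd), the correlation dimension and the fragmentation
indices.  This module provides the Pearson correlation matrix between
indicators, Mann–Whitney U group comparisons, feature preparation
(logit transform of the fragmentation indices, z-scoring, extreme-value
removal) and the nested binary logistic models compared by AIC/BIC:

* Model 1: group ~ age + sex + avg + cov + ac1
* Model 2: Model 1 + correlation dimension
* Model 3: Model 1 + kAR (logit, z-scored)
* Model 4: Model 1 + kRA (logit, z-scored)
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .trace import ValidationError

__all__ = [
    "MEASURE_COLUMNS",
    "MannWhitneyResult",
    "PreparedFeatures",
    "ModelComparison",
    "GroupReport",
    "pearson_correlation_matrix",
    "mann_whitney_u",
    "prepare_features",
    "logistic_models",
    "compare_groups",
    "format_report",
]

#: measures compared between groups, in reporting order
MEASURE_COLUMNS = ("avg", "sd", "cov", "ac1", "corrdim", "k_ar", "k_ra")

_BASE_COVARIATES = ("age", "sex_male", "z_avg", "z_cov", "z_ac1")
_MODEL_EXTRAS = {1: (), 2: ("z_corrdim",), 3: ("z_logit_k_ar",), 4: ("z_logit_k_ra",)}


def pearson_correlation_matrix(
    features: pd.DataFrame, columns: tuple[str, ...] = MEASURE_COLUMNS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    Pairwise-complete observations: for each pair of measures, rows where
    either value is undefined are dropped.  Pairs with fewer than 3
    complete rows or a zero-variance column are NaN.
    """
    cols = [c for c in columns if c in features.columns]
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        pair = features[[a, b]].dropna()
        if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
            r = p = float("nan")
        else:
            res = sps.pearsonr(pair[a], pair[b])
            r, p = float(res.statistic), float(res.pvalue)
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # rank-sum statistic of the first sample
    p: float          # two-sided
    method: str       # "exact" or "asymptotic"


def _exact_mann_whitney(x: np.ndarray, y: np.ndarray) -> MannWhitneyResult:
    # enumeration over all assignments of the pooled midranks
    n1, n2 = x.size, y.size
    pooled = np.concatenate((x, y))
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    dev = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        # tolerance guards against float midranks
        if abs(u - mean_u) >= dev - 1e-9:
            extreme += 1
    return MannWhitneyResult(u=float(u_obs), p=extreme / total, method="exact")


def mann_whitney_u(x, y, method: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test; U is reported for the first sample.

    ``method="auto"`` enumerates the exact permutation distribution of U
    (ties midranked) when the pooled sample has at most 12 observations,
    and otherwise uses the tie-corrected normal approximation (no
    continuity correction, which tracks the exact p more closely at
    these sizes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "exact" or (method == "auto" and x.size + y.size <= 12):
        return _exact_mann_whitney(x, y)
    # no continuity correction: tracks the exact permutation p more closely
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="asymptotic")


@dataclass
class PreparedFeatures:
    """Feature table ready for the logistic models, plus the removal log."""

    table: pd.DataFrame
    removed: pd.DataFrame      # columns: subject_id, column, z
    transform_note: str = (
        "k_ar/k_ra logit-transformed then z-scored; rows with |z| > 2 on a "
        "transformed fragmentation column removed; continuous covariates z-scored"
    )


def _zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=1)
    if not sd > 0:
        raise ValidationError(f"column {col.name!r} has zero variance; cannot z-score")
    return (col - col.mean()) / sd


def prepare_features(features: pd.DataFrame) -> PreparedFeatures:
    """Transform the feature table for regression.

    The fragmentation indices are logit transformed
    (``ln(k / (1 - k))``, requiring k in (0, 1); clamping happens
    upstream) and z-scored; rows with |z| > 2 on a transformed
    fragmentation column are removed and logged.  The correlation
    dimension and the traditional covariates are z-scored as well so the
    odds ratios of all continuous predictors are per-SD.
    """
    df = features.copy()
    if "sex_male" not in df.columns and "sex" in df.columns:
        df["sex_male"] = (df["sex"] == "male").astype(float)
    for col in ("k_ar", "k_ra"):
        vals = df[col]
        bad = vals.notna() & ((vals <= 0) | (vals >= 1))
        if bad.any():
            raise ValidationError(
                f"{col} outside (0, 1) for subjects {df.loc[bad, 'subject_id'].tolist()}; "
                "clamp or drop upstream"
            )
        df[f"logit_{col}"] = np.log(vals / (1.0 - vals))
        df[f"z_logit_{col}"] = _zscore(df[f"logit_{col}"])
    removed_rows = []
    drop_mask = pd.Series(False, index=df.index)
    for col in ("z_logit_k_ar", "z_logit_k_ra"):
        extreme = df[col].abs() > 2.0
        for i in df.index[extreme.fillna(False)]:
            removed_rows.append(
                {"subject_id": df.loc[i, "subject_id"], "column": col, "z": df.loc[i, col]}
            )
        drop_mask |= extreme.fillna(False)
    df = df.loc[~drop_mask].copy()
    for col in ("avg", "cov", "ac1", "corrdim"):
        df[f"z_{col}"] = _zscore(df[col])
    removed = pd.DataFrame(removed_rows, columns=["subject_id", "column", "z"])
    return PreparedFeatures(table=df, removed=removed)


@dataclass
class FittedModel:
    covariates: tuple[str, ...]
    odds_ratios: dict[str, tuple[float, float, float]]  # term -> (OR, lo, hi)
    p_values: dict[str, float]
    aic: float
    bic: float
    log_likelihood: float
    n_used: int
    warnings: tuple[str, ...] = ()


@dataclass
class ModelComparison:
    models: dict[int, FittedModel]

    def aic_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                m: {"AIC": f.aic, "BIC": f.bic, "n": f.n_used}
                for m, f in self.models.items()
            }
        ).T


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> FittedModel:
    import warnings as _warnings

    design = sm.add_constant(X, has_constant="add")
    warnings_: list[str] = []
    model = sm.Logit(y, design)
    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            res = model.fit(disp=0, maxiter=200)
        for w in caught:
            if "separation" in str(w.message).lower():
                warnings_.append("possible_separation")
            elif "converge" in str(w.message).lower():
                warnings_.append("non_convergence")
        if not res.mle_retvals.get("converged", True):
            warnings_.append("non_convergence")
    except Exception as exc:  # e.g. PerfectSeparationError, singular design
        return FittedModel(
            covariates=tuple(X.columns),
            odds_ratios={},
            p_values={},
            aic=float("nan"),
            bic=float("nan"),
            log_likelihood=float("nan"),
            n_used=int(len(X)),
            warnings=(f"fit_failed: {type(exc).__name__}: {exc}",),
        )
    if np.any(np.abs(res.params.values) > 25) or np.any(~np.isfinite(res.bse.values)):
        warnings_.append("possible_separation")
    warnings_ = list(dict.fromkeys(warnings_))
    ors: dict[str, tuple[float, float, float]] = {}
    pvals: dict[str, float] = {}
    ci = res.conf_int(alpha=0.05)
    with np.errstate(over="ignore"):  # separated fits can have infinite ORs
        for term in X.columns:
            ors[term] = (
                float(np.exp(res.params[term])),
                float(np.exp(ci.loc[term, 0])),
                float(np.exp(ci.loc[term, 1])),
            )
            pvals[term] = float(res.pvalues[term])
    return FittedModel(
        covariates=tuple(X.columns),
        odds_ratios=ors,
        p_values=pvals,
        aic=float(res.aic),
        bic=float(res.bic),
        log_likelihood=float(res.llf),
        n_used=int(res.nobs),
        warnings=tuple(warnings_),
    )


def logistic_models(prepared: PreparedFeatures) -> ModelComparison:
    """Fit the four nested logistic models of healthy-group membership.

    The outcome is 1 for healthy, 0 for patient.  Complete separation or
    a singular design is reported in the model's ``warnings`` rather than
    raised.
    """
    df = prepared.table
    too_few = len(df) < 10
    models: dict[int, FittedModel] = {}
    for m, extras in _MODEL_EXTRAS.items():
        cols = list(_BASE_COVARIATES) + list(extras)
        if too_few:
            # a 6-parameter logistic fit on fewer than 10 rows is degenerate;
            # report the model as skipped instead of a meaningless fit
            models[m] = FittedModel(
                covariates=tuple(cols),
                odds_ratios={},
                p_values={},
                aic=float("nan"),
                bic=float("nan"),
                log_likelihood=float("nan"),
                n_used=len(df),
                warnings=(f"too_few_rows: n={len(df)} < 10",),
            )
            continue
        sub = df[cols + ["group"]].dropna()
        yy = (sub["group"] == "healthy").astype(float).to_numpy()
        X = sub[cols]
        constant = [c for c in cols if X[c].nunique() <= 1]
        if constant:
            models[m] = FittedModel(
                covariates=tuple(cols),
                odds_ratios={},
                p_values={},
                aic=float("nan"),
                bic=float("nan"),
                log_likelihood=float("nan"),
                n_used=len(sub),
                warnings=(f"constant_covariates: {constant}",),
            )
            continue
        models[m] = _fit_logit(yy, X)
    return ModelComparison(models=models)


@dataclass
class GroupComparison:
    measure: str
    median_healthy: float
    median_patient: float
    u: float
    p: float
    direction: str  # "healthy_higher" | "healthy_lower" | "none"
    n_healthy: int
    n_patient: int


@dataclass
class GroupReport:
    comparisons: list[GroupComparison]
    correlations: Optional[pd.DataFrame]
    correlation_p: Optional[pd.DataFrame]
    models: Optional[ModelComparison]
    removed: Optional[pd.DataFrame]
    n_healthy: int
    n_patient: int
    model_note: str = ""

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons]).set_index("measure")

    def to_json(self) -> str:
        payload = {
            "n_healthy": self.n_healthy,
            "n_patient": self.n_patient,
            "comparisons": [vars(c) for c in self.comparisons],
            "correlations": None
            if self.correlations is None
            else json.loads(self.correlations.to_json()),
            "correlation_p": None
            if self.correlation_p is None
            else json.loads(self.correlation_p.to_json()),
            "models": None
            if self.models is None
            else {
                str(m): {
                    "covariates": list(f.covariates),
                    "odds_ratios": {k: list(v) for k, v in f.odds_ratios.items()},
                    "p_values": f.p_values,
                    "aic": f.aic,
                    "bic": f.bic,
                    "log_likelihood": f.log_likelihood,
                    "n_used": f.n_used,
                    "warnings": list(f.warnings),
                }
                for m, f in self.models.models.items()
            },
            "removed": None if self.removed is None else self.removed.to_dict("records"),
            "model_note": self.model_note,
        }
        return json.dumps(payload, indent=2, allow_nan=True)


def compare_groups(
    features: pd.DataFrame,
    fit_models: bool = True,
    mwu_method: str = "auto",
) -> GroupReport:
    """Mann–Whitney group comparisons plus correlations and models.

    ``features`` needs one row per subject with ``group`` labels
    ``healthy``/``patient`` (at least 3 subjects each), the measure
    columns, and ``age``/``sex`` when models are fitted.
    """
    for grp in ("healthy", "patient"):
        if (features["group"] == grp).sum() < 3:
            raise ValidationError(f"need >= 3 subjects in group {grp!r}")
    healthy = features[features["group"] == "healthy"]
    patient = features[features["group"] == "patient"]
    comparisons = []
    for measure in MEASURE_COLUMNS:
        if measure not in features.columns:
            continue
        x = healthy[measure].dropna().to_numpy()
        y = patient[measure].dropna().to_numpy()
        res = mann_whitney_u(x, y, method=mwu_method)
        mh, mp = float(np.median(x)), float(np.median(y))
        if mh > mp:
            direction = "healthy_higher"
        elif mh < mp:
            direction = "healthy_lower"
        else:
            direction = "none"
        comparisons.append(
            GroupComparison(
                measure=measure,
                median_healthy=mh,
                median_patient=mp,
                u=res.u,
                p=res.p,
                direction=direction,
                n_healthy=x.size,
                n_patient=y.size,
            )
        )
    rho, pmat = pearson_correlation_matrix(features)
    models = None
    removed = None
    model_note = ""
    if fit_models:
        try:
            prepared = prepare_features(features)
            models = logistic_models(prepared)
            removed = prepared.removed
        except ValidationError as exc:
            model_note = f"logistic models skipped: {exc}"
    return GroupReport(
        comparisons=comparisons,
        correlations=rho,
        correlation_p=pmat,
        models=models,
        removed=removed,
        n_healthy=int(len(healthy)),
        n_patient=int(len(patient)),
        model_note=model_note,
    )


def format_report(report: GroupReport) -> str:
    """Human-readable text summary of the group report."""
    lines = [
        f"Group comparison: {report.n_healthy} healthy vs {report.n_patient} patient subjects",
        "",
        "Mann-Whitney U tests (U for the healthy sample):",
    ]
    for c in report.comparisons:
        lines.append(
            f"  {c.measure:>8}: median healthy={c.median_healthy:.4g} "
            f"patient={c.median_patient:.4g}  U={c.u:.1f}  p={c.p:.3g}  [{c.direction}]"
        )
    if report.correlations is not None:
        lines += ["", "Pearson correlations (p-values in brackets):"]
        cols = list(report.correlations.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                r = report.correlations.loc[a, b]
                p = report.correlation_p.loc[a, b]
                lines.append(f"  {a} ~ {b}: {r:.3f} ({p:.3g})")
    if report.model_note:
        lines += ["", report.model_note]
    if report.models is not None:
        lines += ["", "Logistic models (healthy=1), odds ratios [95% CI]:"]
        for m, fitted in sorted(report.models.models.items()):
            lines.append(f"  Model {m} (n={fitted.n_used}):")
            if fitted.warnings:
                lines.append(f"    warnings: {'; '.join(fitted.warnings)}")
            for term, (or_, lo, hi) in fitted.odds_ratios.items():
                lines.append(
                    f"    {term:>14}: OR={or_:.3g} [{lo:.3g} - {hi:.3g}] "
                    f"p={fitted.p_values[term]:.3g}"
                )
            lines.append(f"    AIC={fitted.aic:.4f}  BIC={fitted.bic:.4f}")
    if report.removed is not None and len(report.removed):
        lines += ["", "Rows removed as extreme (|z| > 2 on transformed fragmentation):"]
        for _, row in report.removed.iterrows():
            lines.append(f"  {row['subject_id']}: {row['column']} z={row['z']:.2f}")
    return "\n".join(lines)
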