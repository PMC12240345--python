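"""Per-subject extraction, cohort analysis and sensitivity sweeps.

Ties the stages together: read an epoch CSV, coarse-grain to the
analysis timescale, compute traditional measures, the correlation
dimension and the fragmentation indices, then assemble the per-subject
feature table and the group-level statistics.  Every output embeds the
resolved configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .corrdim import (
    CorrDimResult,
    CorrelationIntegralCurve,
    EmbeddingConfig,
    correlation_integral_curve,
    estimate_correlation_dimension,
)
from .fragmentation import (
    DEFAULT_LOWESS_FRACTION,
    DEFAULT_THRESHOLD_G,
    FragmentationResult,
    fragmentation_analysis,
    transition_curve_frame,
)
from .preprocess import TraditionalFeatures, coarse_grain, traditional_measures
from .stats import GroupReport, compare_groups, format_report
from .trace import ActivityTrace, ValidationError, read_trace_csv

logger = logging.getLogger("acticomplex")

__all__ = [
    "PipelineConfig",
    "SubjectResult",
    "CohortResult",
    "run_subject",
    "run_cohort",
    "sensitivity_sweep",
]

FEATURE_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "avg",
    "sd",
    "cov",
    "ac1",
    "corrdim",
    "corrdim_r2",
    "k_ar",
    "k_ra",
    "flags",
]


@dataclass
class PipelineConfig:
    """Resolved settings of one analysis run.

    Defaults reproduce the main analysis: 1-minute analysis epochs
    (block-averaged from the source scale), embedding dimension 6 with
    unit delay and Euclidean metric over relative radii 0.03–0.3, a
    0.0167 g binarization cut-off and LOWESS fraction 0.5.
    """

    analysis_epoch_seconds: float = 60.0
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    threshold_g: float = DEFAULT_THRESHOLD_G
    lowess_fraction: float = DEFAULT_LOWESS_FRACTION
    mwu_method: str = "auto"
    fit_models: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "analysis_epoch_seconds": self.analysis_epoch_seconds,
            "embedding": {
                "d": self.embedding.d,
                "tau": self.embedding.tau,
                "metric": self.embedding.metric,
                "r_grid": [float(r) for r in self.embedding.r_grid],
            },
            "threshold_g": self.threshold_g,
            "lowess_fraction": self.lowess_fraction,
            "mwu_method": self.mwu_method,
            "fit_models": self.fit_models,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        emb = data.pop("embedding", {})
        if isinstance(emb, dict):
            emb = dict(emb)
            r_lo = emb.pop("r_min", None)
            r_hi = emb.pop("r_max", None)
            n_r = emb.pop("n_radii", None)
            if r_lo is not None or r_hi is not None or n_r is not None:
                emb["r_grid"] = np.geomspace(
                    r_lo if r_lo is not None else 0.03,
                    r_hi if r_hi is not None else 0.3,
                    int(n_r) if n_r is not None else 20,
                )
            embedding = EmbeddingConfig(**emb)
        else:
            embedding = emb
        known = {f.name for f in dataclasses.fields(cls)} - {"embedding"}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(embedding=embedding, **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_overrides(self, overrides: dict[str, object]) -> "PipelineConfig":
        """Apply dotted ``key=value`` overrides (e.g. ``embedding.d=8``)."""
        data = self.to_dict()
        for key, value in overrides.items():
            parts = key.split(".")
            node = data
            for part in parts[:-1]:
                if part not in node or not isinstance(node[part], dict):
                    raise ValidationError(f"unknown configuration key {key!r}")
                node = node[part]
            leaf = parts[-1]
            # r_min/r_max/n_radii are accepted shorthands for the radius grid
            if len(parts) == 2 and parts[0] == "embedding" and leaf in ("r_min", "r_max", "n_radii"):
                node[leaf] = value
            elif leaf in node:
                node[leaf] = value
            else:
                raise ValidationError(f"unknown configuration key {key!r}")
        return PipelineConfig.from_dict(data)


@dataclass
class SubjectResult:
    subject_id: str
    features: dict
    traditional: TraditionalFeatures
    corr_curve: Optional[CorrelationIntegralCurve]
    corr_dim: Optional[CorrDimResult]
    fragmentation: Optional[FragmentationResult]
    flags: tuple[str, ...]
    config: PipelineConfig

    @property
    def partial(self) -> bool:
        return len(self.flags) > 0


def _analysis_trace(trace: ActivityTrace, config: PipelineConfig) -> ActivityTrace:
    ratio = config.analysis_epoch_seconds / trace.epoch_seconds
    block = int(round(ratio))
    if abs(ratio - block) > 1e-9 or block < 1:
        raise ValidationError(
            f"analysis epoch {config.analysis_epoch_seconds}s is not an integer "
            f"multiple of the source epoch {trace.epoch_seconds}s"
        )
    return coarse_grain(trace, block) if block > 1 else trace


def run_subject(
    trace: ActivityTrace | str | os.PathLike,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str] = None,
) -> SubjectResult:
    """Extract all measures for one subject.

    ``trace`` may be an :class:`ActivityTrace` or a path to an epoch
    CSV.  Degenerate stages (constant series, single-state recordings)
    are flagged and reported as NaN rather than raised, so one subject's
    pathology never aborts a cohort run.  With ``outdir`` set, per-stage
    artifacts are written with the config echoed into every file.
    """
    if config is None:
        config = PipelineConfig()
    if not isinstance(trace, ActivityTrace):
        trace = read_trace_csv(trace)
    analysis = _analysis_trace(trace, config)
    flags: list[str] = []

    trad = traditional_measures(analysis)
    flags.extend(trad.flags)

    curve: Optional[CorrelationIntegralCurve] = None
    cdim: Optional[CorrDimResult] = None
    try:
        curve = correlation_integral_curve(analysis.values, config.embedding)
        cdim = estimate_correlation_dimension(curve)
    except ValidationError as exc:
        flags.append(f"corrdim_undefined: {exc}")

    frag: Optional[FragmentationResult] = None
    try:
        frag = fragmentation_analysis(analysis, config.threshold_g, config.lowess_fraction)
        flags.extend(frag.flags)
    except ValidationError as exc:
        flags.append(f"fragmentation_undefined: {exc}")

    features = {
        "subject_id": trace.subject_id,
        "group": trace.group,
        "age": trace.age,
        "sex": trace.sex,
        "avg": trad.avg,
        "sd": trad.sd,
        "cov": trad.cov,
        "ac1": trad.ac1,
        "corrdim": cdim.nu if cdim is not None else float("nan"),
        "corrdim_r2": cdim.fit_r2 if cdim is not None else float("nan"),
        "k_ar": frag.k_ar if frag is not None else float("nan"),
        "k_ra": frag.k_ra if frag is not None else float("nan"),
        "flags": ";".join(flags),
    }
    result = SubjectResult(
        subject_id=trace.subject_id,
        features=features,
        traditional=trad,
        corr_curve=curve,
        corr_dim=cdim,
        fragmentation=frag,
        flags=tuple(flags),
        config=config,
    )
    if outdir is not None:
        _write_subject_artifacts(result, outdir)
    return result


def _config_comment(config: PipelineConfig) -> str:
    return "config: " + json.dumps(config.to_dict(), sort_keys=True)


def _write_csv_with_config(df: pd.DataFrame, path: str, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_config_comment(config)}\n")
        df.to_csv(fh, index=False)


def _write_subject_artifacts(result: SubjectResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    sid = result.subject_id or "subject"
    config = result.config
    _write_csv_with_config(
        pd.DataFrame([result.features]), os.path.join(outdir, f"{sid}_features.csv"), config
    )
    if result.corr_curve is not None:
        curve = result.corr_curve
        df = pd.DataFrame(
            {
                "d": curve.d,
                "r_relative": curve.r_relative,
                "r_absolute": curve.r_values,
                "C": curve.c_values,
            }
        )
        _write_csv_with_config(df, os.path.join(outdir, f"{sid}_correlation_integral.csv"), config)
    if result.fragmentation is not None:
        frag = result.fragmentation
        for direction, curve, region in (
            ("AR", frag.ar_curve, frag.ar_region),
            ("RA", frag.ra_curve, frag.ra_region),
        ):
            if curve is None:
                continue
            df = transition_curve_frame(curve, region)
            _write_csv_with_config(
                df, os.path.join(outdir, f"{sid}_transition_{direction}.csv"), config
            )
    summary = {
        "config": config.to_dict(),
        "subject_id": sid,
        "features": {k: v for k, v in result.features.items()},
    }
    with open(os.path.join(outdir, f"{sid}_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


@dataclass
class CohortResult:
    features: pd.DataFrame
    report: Optional[GroupReport]
    exclusions: pd.DataFrame   # subject_id, reason
    config: PipelineConfig


def _load_manifest(manifest: str | os.PathLike | pd.DataFrame) -> tuple[pd.DataFrame, str]:
    if isinstance(manifest, pd.DataFrame):
        return manifest.copy(), os.getcwd()
    df = pd.read_csv(manifest, comment="#")
    required = {"subject_id", "group", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing column(s) {sorted(missing)}")
    return df, os.path.dirname(os.fspath(manifest))


def run_cohort(
    manifest: str | os.PathLike | pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str] = None,
) -> CohortResult:
    """Run the full pipeline over a cohort manifest.

    Subjects whose extraction fails are excluded and listed in the
    result; the group statistics run on the remainder.
    """
    if config is None:
        config = PipelineConfig()
    df, base = _load_manifest(manifest)
    rows = []
    exclusions = []
    for _, meta in df.iterrows():
        sid = str(meta["subject_id"])
        try:
            path = meta["path"]
            if not os.path.isabs(path):
                path = os.path.join(base, path)
            trace = read_trace_csv(
                path,
                subject_id=sid,
                group=meta.get("group"),
                age=float(meta["age"]) if "age" in meta and pd.notna(meta["age"]) else None,
                sex=meta.get("sex"),
            )
            result = run_subject(trace, config)
            rows.append(result.features)
            logger.info("subject %s extracted (%d flags)", sid, len(result.flags))
        except (ValidationError, OSError) as exc:
            exclusions.append({"subject_id": sid, "reason": str(exc)})
            logger.warning("subject %s excluded: %s", sid, exc)
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    report: Optional[GroupReport] = None
    if len(features):
        try:
            report = compare_groups(
                features, fit_models=config.fit_models, mwu_method=config.mwu_method
            )
        except ValidationError as exc:
            logger.warning("group statistics skipped: %s", exc)
    excl = pd.DataFrame(exclusions, columns=["subject_id", "reason"])
    result = CohortResult(features=features, report=report, exclusions=excl, config=config)
    if outdir is not None:
        _write_cohort_artifacts(result, outdir)
    return result


def _write_cohort_artifacts(result: CohortResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    _write_csv_with_config(result.features, os.path.join(outdir, "features.csv"), result.config)
    _write_csv_with_config(result.exclusions, os.path.join(outdir, "exclusions.csv"), result.config)
    if result.report is not None:
        payload = json.loads(result.report.to_json())
        payload["config"] = result.config.to_dict()
        with open(os.path.join(outdir, "group_report.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        with open(os.path.join(outdir, "group_report.txt"), "w") as fh:
            fh.write(f"# {_config_comment(result.config)}\n")
            fh.write(format_report(result.report) + "\n")


def sensitivity_sweep(
    manifest: str | os.PathLike | pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    grid: Optional[dict[str, list]] = None,
    outdir: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run the per-subject extraction over a grid of parameter overrides.

    ``grid`` maps dotted config keys (``embedding.d``, ``embedding.metric``,
    ``embedding.r_min``, ``embedding.r_max``, ``embedding.tau``,
    ``analysis_epoch_seconds``, ``threshold_g``, ...) to lists of values;
    the swept cells are the cartesian product, with the unmodified config
    always included as cell ``default``.  Returns a long-format table
    (one row per subject x cell) and a summary of Spearman rank
    correlations of each measure between every cell and the default cell
    — the qualitative-robustness check that parameter changes reorder
    subjects little.
    """
    import itertools as it

    if config is None:
        config = PipelineConfig()
    grid = grid or {}
    keys = sorted(grid)
    cells: list[tuple[str, PipelineConfig]] = [("default", config)]
    for combo in it.product(*(grid[k] for k in keys)) if keys else ():
        overrides = dict(zip(keys, combo))
        label = ",".join(f"{k}={v}" for k, v in overrides.items())
        try:
            cells.append((label, config.with_overrides(overrides)))
        except ValidationError as exc:
            logger.warning("sweep cell %s skipped: %s", label, exc)

    df, base = _load_manifest(manifest)
    traces = []
    for _, meta in df.iterrows():
        path = meta["path"]
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        try:
            traces.append(
                read_trace_csv(path, subject_id=str(meta["subject_id"]), group=meta.get("group"))
            )
        except (ValidationError, OSError) as exc:
            logger.warning("sweep: subject %s skipped: %s", meta["subject_id"], exc)

    rows = []
    for label, cell_config in cells:
        for trace in traces:
            try:
                features = run_subject(trace, cell_config).features
            except ValidationError as exc:
                logger.warning("sweep cell %s subject %s failed: %s", label, trace.subject_id, exc)
                continue
            row = {"cell": label, **features}
            rows.append(row)
    long_df = pd.DataFrame(rows)

    summaries = []
    measures = ("avg", "cov", "ac1", "corrdim", "k_ar", "k_ra")
    default_block = long_df[long_df["cell"] == "default"].set_index("subject_id")
    for label, _ in cells[1:]:
        block = long_df[long_df["cell"] == label].set_index("subject_id")
        joined = default_block.join(block, lsuffix="_default", rsuffix="_cell", how="inner")
        for measure in measures:
            a = joined[f"{measure}_default"]
            b = joined[f"{measure}_cell"]
            ok = a.notna() & b.notna()
            if ok.sum() >= 3:
                rho = float(sps_spearman(a[ok], b[ok]))
            else:
                rho = float("nan")
            summaries.append({"cell": label, "measure": measure, "spearman_vs_default": rho})
    summary_df = pd.DataFrame(summaries, columns=["cell", "measure", "spearman_vs_default"])
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        _write_csv_with_config(long_df, os.path.join(outdir, "sweep_long.csv"), config)
        _write_csv_with_config(summary_df, os.path.join(outdir, "sweep_summary.csv"), config)
    return long_df, summary_df


def sps_spearman(a, b) -> float:
    from scipy.stats import spearmanr

    return spearmanr(a, b).statistic
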