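"""End-to-end analysis pipeline: metrics -> screen -> prune -> select -> fit
-> evaluate, with all reports written to an output directory.

Every artifact carries a provenance header (config hash + seed, no
timestamps), so a rerun with the same configuration and seed produces a
byte-identical report bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import read_cohort
from .dvh import DEFAULT_THRESHOLDS, metrics_table, read_dvh, vx_column
from .evaluation import calibration_bins, model_rs, roc_auc, youden_cutoff
from .lkb import LKBModel, LKBParameters
from .logistic import LogisticNTCP, LogisticNTCPModel
from .selection import bootstrap_select, prune_correlated, spearman_matrix, spearman_screen

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "PipelineError"]

#: Cohort columns that are identifiers/outcome, never candidate covariates.
_NON_CANDIDATES = {"patient_id", "late_gi"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    cohort_path: str
    outdir: str
    dvh_path: str | None = None
    thresholds: tuple = DEFAULT_THRESHOLDS
    prune_threshold: float = 0.75
    n_boot: int = 500
    max_order: int = 3
    n_bins: int = 5
    seed: int = 0
    oob: bool = False
    lkb: LKBParameters | None = None
    overwrite: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.prune_threshold <= 1.0:
            raise ValueError("prune_threshold must be in (0, 1]")
        if self.n_boot < 1 or self.max_order < 1 or self.n_bins < 1:
            raise ValueError("n_boot, max_order and n_bins must be positive")

    def digest(self) -> str:
        """Short stable hash of the analysis parameters.

        Covers everything that affects the computed numbers (thresholds,
        pruning, bootstrap settings, seed, LKB parameters) but not file
        locations, so reruns of the same analysis are byte-identical
        regardless of where inputs and outputs live.
        """
        payload = dataclasses.asdict(self)
        for key in ("cohort_path", "dvh_path", "outdir", "overwrite"):
            payload.pop(key, None)
        if self.lkb is not None:
            payload["lkb"] = dataclasses.asdict(self.lkb)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig) -> str:
    return f"# ntcpkit config={config.digest()} seed={config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, index=False)


def _write_text(text: str, path: Path, config: RunConfig) -> None:
    path.write_text(_provenance(config) + text + "\n")


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the complete NTCP analysis chain and write the report bundle.

    Stages: (optional) DVH metric extraction, univariate Spearman screening,
    cross-correlation pruning, bootstrap model selection, logistic fits of
    the selected and the V65-only model, optional LKB comparator, and
    ROC/Youden/calibration evaluation of every model.  Returns a mapping
    from artifact label to written path.
    """
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.overwrite:
        raise PipelineError(f"output: directory {outdir} is not empty (use overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- inputs ------------------------------------------------------------
    cohort_path = Path(config.cohort_path)
    if not cohort_path.exists():
        raise PipelineError(f"input: cohort file not found: {cohort_path}")
    df = read_cohort(cohort_path)
    curves = None
    if config.dvh_path is not None:
        dvh_path = Path(config.dvh_path)
        if not dvh_path.exists():
            raise PipelineError(f"input: DVH file not found: {dvh_path}")
        curves = read_dvh(dvh_path)
        metrics = metrics_table(curves, config.thresholds)
        df = df.drop(columns=[c for c in metrics.columns if c != "patient_id" and c in df], errors="ignore")
        df = df.merge(metrics, on="patient_id", validate="one_to_one")
    n, events = len(df), int(df["late_gi"].sum())
    logger.info("cohort: n=%d, late events=%d (%.1f%%)", n, events, 100 * events / n)

    candidates = [
        c for c in df.columns
        if c not in _NON_CANDIDATES and pd.api.types.is_numeric_dtype(df[c])
    ]

    # --- univariate screen + pruning ---------------------------------------
    screen = spearman_screen(df, candidates)
    uni = pd.DataFrame(
        [{"variable": r.variable, "rs": r.rs, "pvalue": r.pvalue, "degenerate": r.degenerate}
         for r in screen]
    )
    _write_csv(uni, outdir / "univariate.csv", config)
    artifacts["univariate"] = outdir / "univariate.csv"

    corr = spearman_matrix(df, candidates)
    _write_csv(corr.rename_axis("variable").reset_index(), outdir / "correlation_matrix.csv", config)
    artifacts["correlation_matrix"] = outdir / "correlation_matrix.csv"

    pool = prune_correlated(df, candidates, screen, config.prune_threshold)
    logger.info("pruned %d -> %d candidates: %s", len(candidates), len(pool), ", ".join(pool))

    # --- bootstrap selection ------------------------------------------------
    try:
        report = bootstrap_select(
            df, pool, n_boot=config.n_boot,
            max_order=min(config.max_order, len(pool)),
            seed=config.seed, oob=config.oob,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"selection: {exc}") from exc
    _write_csv(report.to_frame(), outdir / "selection_models.csv", config)
    _write_text(report.summary(), outdir / "selection_report.txt", config)
    artifacts["selection_models"] = outdir / "selection_models.csv"
    artifacts["selection_report"] = outdir / "selection_report.txt"
    logger.info("chosen order %d, model %s", report.chosen_order, "+".join(report.chosen_model))

    # --- model fits ---------------------------------------------------------
    models: dict[str, LogisticNTCPModel] = {}
    try:
        res = LogisticNTCP.from_dataframe(df, "late_gi", list(report.chosen_model)).fit()
        models["selected"] = res.model_spec
        res.model_spec.save(outdir / "model_selected.json")
        artifacts["model_selected"] = outdir / "model_selected.json"
        logger.info("selected model fit:\n%s", res.summary())
        if "v65" in df.columns and list(report.chosen_model) != ["v65"]:
            res_v65 = LogisticNTCP.from_dataframe(df, "late_gi", ["v65"]).fit()
            models["v65_only"] = res_v65.model_spec
            res_v65.model_spec.save(outdir / "model_v65.json")
            artifacts["model_v65"] = outdir / "model_v65.json"
    except Exception as exc:
        raise PipelineError(f"fit: {exc}") from exc

    # --- predictions ---------------------------------------------------------
    predictions: dict[str, np.ndarray] = {
        label: np.asarray(m.ntcp(df)) for label, m in models.items()
    }
    if config.lkb is not None and curves is not None:
        lkb = LKBModel(config.lkb)
        by_id = {c.patient_id: c for c in curves}
        predictions["lkb"] = np.array(
            [lkb.ntcp(by_id[pid]) for pid in df["patient_id"].astype(str)]
        )

    # --- evaluation ----------------------------------------------------------
    y = df["late_gi"].to_numpy(dtype=float)
    rows = []
    for label, pred in predictions.items():
        roc = roc_auc(pred, y)
        rs = model_rs(pred, y)
        row = {
            "model": label,
            "rs": rs,
            "auc": roc.auc,
            "youden_threshold": roc.youden_threshold,
            "youden_j": roc.youden_j,
        }
        if label == "v65_only":
            row["youden_v65_pct"] = youden_cutoff(roc, df["v65"].to_numpy(), pred)
        rows.append(row)
        bins = calibration_bins(pred, y, min(config.n_bins, len(df) // 2))
        _write_csv(bins.to_frame(), outdir / f"calibration_{label}.csv", config)
        artifacts[f"calibration_{label}"] = outdir / f"calibration_{label}.csv"
        logger.info("model %s: Rs=%.3f AUC=%.3f", label, rs, roc.auc)
    _write_csv(pd.DataFrame(rows), outdir / "evaluation.csv", config)
    artifacts["evaluation"] = outdir / "evaluation.csv"

    _write_text(
        "\n".join([
            f"n = {n}",
            f"late events = {events}",
            f"candidates = {len(candidates)}",
            f"pruned pool = {', '.join(pool)}",
            f"chosen model = {' + '.join(report.chosen_model)}",
        ]),
        outdir / "run_info.txt",
        config,
    )
    artifacts["run_info"] = outdir / "run_info.txt"
    return artifacts
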