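"""End-to-end orchestration: per-subject extraction and cohort analysis.

``run_subject`` carries one recording from waveform (or RR file) to the
per-scale entropies and complexity indices; ``run_cohort`` combines the
group statistics and the One-R classification into one report, written
as mutually consistent JSON and TSV, with the frozen configuration and a
log stored alongside for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import signal_ingest as si
from .group_stats import mann_whitney_exact, spearman
from .multiscale_entropy import (
    EntropyParams,
    MCS_LABEL,
    UWS_LABEL,
    complexity_indices,
    mse_curve,
)
from .oner import (
    CohortTable,
    cross_validate,
    evaluate,
    fit_oner,
    fit_zeror,
    predict,
)

logger = logging.getLogger("hrvc")

__all__ = ["RunConfig", "PipelineError", "run_subject", "run_cohort"]

#: Order of the metric rows in the printed classification panel.
PANEL_ROWS = (
    "sensitivity",
    "specificity",
    "fnr",
    "fpr",
    "precision_mcs",
    "precision_uws",
    "accuracy",
    "f1",
    "mcc",
)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and subject."""

    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")
        self.stage = stage
        self.subject = subject
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    input_path: str | None = None
    input_kind: str = "auto"  # auto | waveform | rr
    sampling_rate: float | None = None
    channel: str = "ecg"
    passband: tuple = (0.5, 40.0)
    segment_duration: float = 600.0
    segment_offset: float = 0.0
    ectopic_deviation: float = 0.20
    ectopic_window: int = 11
    ectopic_action: str = "flag"
    entropy_m: int = 2
    entropy_r: float = 0.15
    max_scale: int = 10
    r_convention: str = "fixed_scale1_sd"
    features: tuple = ("ci_s", "ci_l")
    cv_folds: int = 10
    stratified: bool = True
    min_bucket: int = 6
    seed: int = 0
    output_dir: str | None = None
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def entropy_params(self) -> EntropyParams:
        return EntropyParams(
            m=self.entropy_m,
            r=self.entropy_r,
            max_scale=self.max_scale,
            r_convention=self.r_convention,
        )

    def freeze(self, out_dir: Path) -> None:
        """Write the configuration verbatim into the output directory."""
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self)
        cfg["passband"] = list(self.passband)
        cfg["features"] = list(self.features)
        (out_dir / "config.json").write_text(json.dumps(cfg, indent=2, default=str))


def _setup_logging(config: RunConfig, out_dir: Path | None) -> None:
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    if out_dir is not None and not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (out_dir / "run.log")
        for h in logger.handlers
    ):
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)


def run_subject(config: RunConfig, subject_id: str = "subject") -> dict:
    """Run one recording through the full extraction + entropy pipeline.

    RR-file input skips detection and goes straight to screening and
    entropy; waveform input runs filter -> detect -> intervals -> screen
    -> segment -> entropy.  Returns the per-subject record with the
    per-scale entropies, complexity indices, and QC flags.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    _setup_logging(config, out_dir)
    if config.input_path is None:
        raise PipelineError("input", subject_id, ValueError("no input path configured"))

    path = Path(config.input_path)
    kind = config.input_kind
    if kind == "auto":
        kind = "rr" if path.suffix.lower() in (".rr", ".ibi", ".txt") else "waveform"

    try:
        if kind == "rr":
            ibi = si.read_ibi(path)
        else:
            wave = si.read_waveform(path, sampling_rate=config.sampling_rate, channel=config.channel)
            wave = si.fft_filter(wave, config.passband)
            method = "ppg_pulse" if config.channel == "ppg" else "ecg_qrs"
            beats = si.detect_beats(wave, method=method)
            ibi = si.to_ibi(beats)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError("signal_ingest", subject_id, exc) from exc

    try:
        screened = si.screen_ectopics(
            ibi,
            deviation_fraction=config.ectopic_deviation,
            window=config.ectopic_window,
            action=config.ectopic_action,
        )
    except Exception as exc:
        raise PipelineError("screen_ectopics", subject_id, exc) from exc

    try:
        segment = si.extract_segment(
            screened, duration=config.segment_duration, offset=config.segment_offset
        )
    except Exception as exc:
        raise PipelineError("extract_segment", subject_id, exc) from exc

    try:
        curve = mse_curve(segment, config.entropy_params())
        ci = complexity_indices(curve, strict=False)
    except Exception as exc:
        raise PipelineError("multiscale_entropy", subject_id, exc) from exc

    record = {
        "subject_id": subject_id,
        "n_intervals": segment.n,
        "sd_ref": curve.sd_ref,
        **{f"se_scale_{t}": (float(s) if d else None)
           for t, s, d in zip(curve.scales, curve.se, curve.defined)},
        "ci_s": ci.ci_s,
        "ci_l": ci.ci_l,
        "flagged_fraction": segment.flagged_fraction,
        "undefined_scales": [int(t) for t, d in zip(curve.scales, curve.defined) if not d],
    }
    logger.info("subject %s: ci_s=%.3f ci_l=%.3f", subject_id, ci.ci_s, ci.ci_l)
    if out_dir is not None:
        config.freeze(out_dir)
        (out_dir / f"{subject_id}.json").write_text(json.dumps(record, indent=2))
    return record


def _panel(report) -> dict:
    full = report.as_dict()
    disp = report.as_dict(rounded=True)
    return {
        "counts": {k: full[k] for k in ("tp", "fn", "fp", "tn")},
        "rates": {k: full[k] for k in PANEL_ROWS},
        "display": {k: disp[k] for k in PANEL_ROWS},
    }


def run_cohort(cohort, config: RunConfig | None = None) -> dict:
    """Full cohort analysis: group statistics plus classification panels.

    ``cohort`` is a :class:`CohortTable` or a path to a cohort CSV with
    columns subject_id, diagnosis, crs_r_total, ci_s, ci_l.  The report
    contains Mann-Whitney and Spearman results for both indices, the
    fitted One-R rule, the Zero-R baseline, and full-training plus
    k-fold metric panels; it is written as JSON and TSV when an output
    directory is configured.
    """
    config = config or RunConfig()
    out_dir = Path(config.output_dir) if config.output_dir else None
    _setup_logging(config, out_dir)
    if not isinstance(cohort, CohortTable):
        cohort = CohortTable.from_csv(cohort)

    labels = cohort.diagnoses
    if len(set(labels)) < 2:
        raise PipelineError("run_cohort", cohort.name, ValueError("single-class cohort"))

    stats: dict = {}
    for feat in ("ci_s", "ci_l"):
        vals = cohort.values(feat)
        mcs, uws = vals[labels == MCS_LABEL], vals[labels == UWS_LABEL]
        mw = mann_whitney_exact(mcs, uws)
        stats[f"mann_whitney_{feat}"] = {
            "U": mw.statistic, "z": mw.z, "p": mw.p_value, "exact": mw.exact,
            "median_mcs": float(np.median(mcs)), "median_uws": float(np.median(uws)),
        }
        crs = np.array([r.crs_r_total for r in cohort.records], dtype=float)
        if not np.isnan(crs).any():
            sp = spearman(crs, vals)
            stats[f"spearman_crs_r_{feat}"] = {"rho": sp.statistic, "p": sp.p_value}

    model = fit_oner(cohort, features=config.features, min_bucket=config.min_bucket)
    preds = [predict(model, r) for r in cohort.records]
    full_report = evaluate(preds, list(labels))
    pooled, _folds = cross_validate(
        cohort,
        k=config.cv_folds,
        stratified=config.stratified,
        seed=config.seed,
        features=config.features,
        min_bucket=config.min_bucket,
    )
    zeror = fit_zeror(cohort)
    zr_preds = [predict(zeror, r) for r in cohort.records]
    zr_report = evaluate(zr_preds, list(labels))

    report = {
        "cohort": cohort.name,
        "n": len(cohort),
        "statistics": stats,
        "one_r": {
            "attribute": model.attribute,
            "boundaries": list(model.boundaries),
            "bin_labels": list(model.bin_labels),
            "training_error": model.training_error,
            "rule": model.rule_text(),
        },
        "zero_r": {"label": zeror.bin_labels[0], "accuracy": zr_report.accuracy},
        "full_training": _panel(full_report),
        "cross_validation": {"k": config.cv_folds, "seed": config.seed, **_panel(pooled)},
    }
    logger.info("cohort %s: rule=%s", cohort.name, report["one_r"]["rule"])

    if out_dir is not None:
        config.freeze(out_dir)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        rows = []
        for metric in PANEL_ROWS:
            rows.append(
                {
                    "metric": metric,
                    "full_training": report["full_training"]["rates"][metric],
                    "cross_validation": report["cross_validation"]["rates"][metric],
                }
            )
        pd.DataFrame(rows).to_csv(out_dir / "report.tsv", sep="\t", index=False)
    return report
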