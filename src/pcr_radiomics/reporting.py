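"""Run configuration, pipeline commands and report rendering.

Ties the stages into the validation workflow: simulate -> extract -> score
-> validate.  Every artefact embeds the configuration echo and its hash so
two runs with equal configs are comparable; the published-threshold block is
always rendered before the locally re-optimised Youden block, because under
external-validation semantics the cut-off is part of the model under test.

Exit codes: 0 success, 3 partial extraction, >= 4 fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import PcrRadiomicsError
from .evaluation import ValidationReport, subgroup_validation
from .imaging_io import (
    CohortTable,
    read_cohort_table,
    read_feature_table,
    read_mask,
    read_volume,
    write_feature_table,
    write_mask,
    write_volume,
)
from .model import ModelSpec, PatientRecord, default_model_spec, load_model_spec, predict_pcr_probability
from .radiomics import FeatureConfig, compute_signature_features
from .synthetic_data import CohortSpec, sample_cohort

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_PARTIAL = 3
EXIT_FATAL = 4


@dataclass
class RunConfig:
    """Serialisable run settings, echoed verbatim into every output."""

    cohort_table: str | None = None
    image_dir: str | None = None
    mask_dir: str | None = None
    output_dir: str = "out"
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    model_spec_path: str | None = None  # None -> packaged default
    threshold_override: float | None = None
    ci_level: float = 0.95
    auc_ci_method: str = "delong"
    subgroup_variable: str = "field_strength"
    seed: int = 0
    cohort_spec: CohortSpec | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_config"] = self.feature_config.to_dict()
        d["cohort_spec"] = self.cohort_spec.to_dict() if self.cohort_spec else None
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def resolve_model(self) -> ModelSpec:
        spec = (
            load_model_spec(self.model_spec_path)
            if self.model_spec_path
            else default_model_spec()
        )
        if self.threshold_override is not None:
            spec = ModelSpec(**{**spec.to_dict(), "threshold": self.threshold_override})
        return spec

    def provenance(self) -> dict:
        return {
            "config": self.to_dict(),
            "config_hash": self.config_hash(),
            "package_version": __version__,
        }


# ---------------------------------------------------------------------------
# commands


def cmd_simulate(config: RunConfig, with_images: bool = True, force: bool = False) -> int:
    """Write a simulated cohort (CSV + optional volume/mask pairs + manifest)."""
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        logger.error("output dir %s exists and is non-empty (use force)", out)
        return EXIT_FATAL
    out.mkdir(parents=True, exist_ok=True)
    spec = config.cohort_spec or CohortSpec(seed=config.seed)
    model = config.resolve_model()
    table, phantoms = sample_cohort(
        spec, model, with_images=with_images, feature_config=config.feature_config
    )
    df = table.df.copy()
    if with_images:
        (out / "images").mkdir(exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)
        vol_paths, mask_paths = [], []
        for pid, (pspec, vol, msk) in zip(df["id"], phantoms):
            vp = out / "images" / f"{pid}.nii.gz"
            mp = out / "masks" / f"{pid}.nii.gz"
            write_volume(vol, vp)
            write_mask(msk, mp)
            vol_paths.append(str(vp.relative_to(out)))
            mask_paths.append(str(mp.relative_to(out)))
        df["volume_path"] = vol_paths
        df["mask_path"] = mask_paths
    cohort_csv = out / "cohort.csv"
    df.to_csv(cohort_csv, index=False)
    manifest = {
        "seed": spec.seed,
        "cohort_spec": spec.to_dict(),
        "n": int(len(df)),
        "n_positive": int(df["pcr_label"].sum()),
        "cohort_sha256": hashlib.sha256(cohort_csv.read_bytes()).hexdigest(),
        **config.provenance(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("simulated %d patients (%d pCR) into %s", len(df),
                int(df["pcr_label"].sum()), out)
    return EXIT_OK


def cmd_extract(config: RunConfig) -> int:
    """Extract both radiomic features for every cohort row with images."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_cohort_table(config.cohort_table)
    base = Path(config.cohort_table).parent
    rows, failures = [], []
    for _, r in table.df.iterrows():
        try:
            vol_path = base / r["volume_path"]
            mask_path = base / r["mask_path"]
            vol = read_volume(vol_path)
            msk = read_mask(mask_path, vol)
            fv = compute_signature_features(vol, msk, config.feature_config)
            rows.append({
                "id": r["id"], "cT": r["cT"], "cN": r["cN"],
                "field_strength": r["field_strength"],
                "skewness": fv.skewness, "entropy": fv.entropy,
                "score": np.nan, "pcr_label": r["pcr_label"],
            })
        except (PcrRadiomicsError, OSError, KeyError) as exc:
            failures.append((r["id"], str(exc)))
            logger.warning("extraction failed for %s: %s", r["id"], exc)
    if not rows:
        logger.error("zero successful extractions")
        return EXIT_FATAL
    write_feature_table(pd.DataFrame(rows), out / "features.csv")
    if failures:
        (out / "extraction_failures.json").write_text(json.dumps(
            [{"id": i, "error": e} for i, e in failures], indent=2))
    logger.info("extracted features for %d/%d patients", len(rows), table.n)
    return EXIT_PARTIAL if failures else EXIT_OK


def cmd_score(config: RunConfig, features_csv=None) -> int:
    """Apply the logistic model to an extracted feature table."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = Path(features_csv) if features_csv else out / "features.csv"
    df = read_feature_table(path)
    model = config.resolve_model()
    scores = []
    for _, r in df.iterrows():
        rec = PatientRecord(id=r["id"], cT=int(r["cT"]), cN=int(r["cN"]),
                            skewness=r["skewness"], entropy=r["entropy"])
        scores.append(predict_pcr_probability(rec, model))
    df["score"] = scores
    write_feature_table(df, out / "features_scored.csv")
    logger.info("scored %d patients (mean score %.3f)", len(df), float(np.mean(scores)))
    return EXIT_OK


def cmd_validate(config: RunConfig, features_csv=None) -> int:
    """Full validation report (JSON + Markdown + ROC CSV + ROC plot)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = Path(features_csv) if features_csv else out / "features_scored.csv"
    df = read_feature_table(path)
    if df["pcr_label"].isna().any():
        logger.error("missing labels in rows %s",
                     df.index[df["pcr_label"].isna()].tolist())
        return EXIT_FATAL
    if df["score"].isna().any():
        logger.error("missing scores; run score first")
        return EXIT_FATAL
    model = config.resolve_model()
    report = subgroup_validation(
        df["score"].to_numpy(), df["pcr_label"].to_numpy(),
        df[config.subgroup_variable].to_numpy(),
        published_threshold=model.threshold,
        level=config.ci_level, auc_ci_method=config.auc_ci_method,
        seed=config.seed,
    )
    report.config = config.provenance()
    (out / "validation_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True))
    (out / "validation_report.md").write_text(render_markdown(report))
    if report.roc is not None:
        pd.DataFrame(report.roc, columns=["fpr", "tpr", "threshold"]).to_csv(
            out / "roc.csv", index=False)
        _plot_roc(report, out / "roc.png")
    logger.info("validation report written to %s (AUC=%s)", out, report.auc)
    return EXIT_OK


def cmd_recover(config: RunConfig, n: int = 5000, n_seeds: int = 3) -> int:
    """Parameter-recovery experiment: refit the generating model by MLE."""
    from .synthetic_data import parameter_recovery_experiment

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = config.resolve_model()
    frames = []
    for k in range(n_seeds):
        res = parameter_recovery_experiment(n, config.seed + k, model)
        res.insert(0, "seed", config.seed + k)
        frames.append(res)
    pd.concat(frames).to_csv(out / "parameter_recovery.csv", index=False)
    return EXIT_OK


# ---------------------------------------------------------------------------
# rendering


def _fmt_metric(m) -> str:
    if m.value is None:
        return f"undefined ({m.undefined_reason})"
    lo, hi = m.ci
    return f"{m.value:.2f} ({lo:.2f}-{hi:.2f})"


def render_markdown(report: ValidationReport) -> str:
    """Human-readable summary mirroring a published performance table."""
    lines = ["# Validation report", ""]
    lines.append(f"- patients: {report.n} ({report.n_positive} pCR, "
                 f"prevalence {100 * report.n_positive / report.n:.1f}%)")
    if report.auc is not None:
        ci = f" (95% CI {report.auc_ci[0]:.2f}-{report.auc_ci[1]:.2f}, {report.auc_ci_method})" \
            if report.auc_ci else ""
        lines.append(f"- AUC: {report.auc:.2f}{ci}")
    for flag in report.flags:
        lines.append(f"- flag: {flag}")
    cols = ["pooled"] + [f"subgroup {k}" for k in report.subgroups]
    for block_idx, block in enumerate(report.blocks):
        lines += ["", f"## Threshold = {block.threshold:.3f} ({block.label})", ""]
        sub_blocks = []
        for key, sub in report.subgroups.items():
            match = [b for b in sub.blocks if b.label == block.label]
            sub_blocks.append(match[0] if match else None)
        header = "| Parameter | " + " | ".join(cols) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(cols) + 1))
        for name in ("accuracy", "specificity", "sensitivity", "npv", "ppv"):
            cells = [_fmt_metric(block.metrics[name])]
            for sb in sub_blocks:
                cells.append(_fmt_metric(sb.metrics[name]) if sb else "n/a")
            lines.append(f"| {name} | " + " | ".join(cells) + " |")
        kap = [block] + sub_blocks
        cells = []
        for b in kap:
            if b is None or b.kappa is None:
                cells.append("undefined")
            else:
                cells.append(f"{b.kappa:.2f} ({b.kappa_ci[0]:.2f}-{b.kappa_ci[1]:.2f})")
        lines.append("| kappa | " + " | ".join(cells) + " |")
    if report.config:
        lines += ["", f"config hash: `{report.config.get('config_hash', 'n/a')}`",
                  f"package version: {report.config.get('package_version', 'n/a')}"]
    return "\n".join(lines) + "\n"


def _plot_roc(report: ValidationReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    roc = np.asarray(report.roc)
    ax.plot(roc[:, 0], roc[:, 1], drawstyle="steps-post", label="pooled")
    for key, sub in report.subgroups.items():
        if sub.roc is not None:
            r = np.asarray(sub.roc)
            ax.plot(r[:, 0], r[:, 1], drawstyle="steps-post", alpha=0.6,
                    label=f"{key}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if report.auc is not None:
        ax.set_title(f"ROC (AUC = {report.auc:.2f})")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
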