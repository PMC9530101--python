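"""End-to-end orchestration: rigid align, deformable register, quantify, test.

A cohort lives on disk as one directory per subject::

    <input_root>/subject_000/meta.yaml          # subject_id, laterality
    <input_root>/subject_000/<condition>/volume.nii.gz
    <input_root>/subject_000/<condition>/tibia.nii.gz
    <input_root>/subject_000/<condition>/meniscus_medial.nii.gz
    <input_root>/subject_000/<condition>/meniscus_lateral.nii.gz

One condition (default: the first listed) is the template; every other
condition is registered to it (stage 1: tibia-masked rigid; stage 2:
deformable on the joint meniscus masks), the field is cropped with the
template meniscus masks, segments are derived once per subject from the
template masks, and per-segment motion rows are accumulated into a tidy
CSV.  Cohort statistics then build the summary and comparison tables and
a Markdown report with per-segment vector plots.

Everything is deterministic: re-running with the same config reproduces
the CSV outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, PairingError
from .grids import GridTransform, LabelMask, load_mask, load_volume, resample, save_mask
from .motion import anatomical_axes, crop_field, partition_arch, segment_motion
from .phantom import _save_field
from .registration import (
    MultilevelSchedule,
    ObjectiveWeights,
    register_deformable,
    register_rigid,
)

logger = logging.getLogger("meniscusmotion")

__all__ = ["RunConfig", "run_subject", "run_cohort", "write_report"]

MASK_FILES = ("tibia", "meniscus_medial", "meniscus_lateral")
MOTION_COLUMNS = [
    "subject", "laterality", "condition", "meniscus", "segment",
    "avg_mm", "ml_mm", "ap_mm", "n_voxels",
]


@dataclass
class RunConfig:
    """Configuration of a cohort run (YAML-serialisable)."""

    input_root: str
    output_root: str
    template_condition: str = "neutral"
    conditions: tuple = ("internal", "external")
    alpha: float = 0.1
    beta: float = 0.05
    levels: int = 3
    max_iter: int = 12
    tol_rel: float = 1e-4
    smoothing_sigma: float = 1.0
    seed: int = 0
    allow_partial: bool = False

    @property
    def weights(self) -> ObjectiveWeights:
        return ObjectiveWeights(alpha=self.alpha, beta=self.beta)

    @property
    def schedule(self) -> MultilevelSchedule:
        return MultilevelSchedule(
            n_levels=self.levels,
            max_iter_per_level=self.max_iter,
            tol_rel=self.tol_rel,
            smoothing_sigma=self.smoothing_sigma,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        # a nested `registration:` block (alpha, beta, levels, max_iter,
        # tol_rel, smoothing_sigma) is accepted as an alias for the flat keys
        for key, val in raw.pop("registration", {}).items():
            raw.setdefault(key, val)
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return RunConfig(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _subject_dirs(root: Path) -> List[Path]:
    return sorted(p for p in root.iterdir() if p.is_dir() and p.name.startswith("subject_"))


def _require(path: Path) -> Path:
    if not path.exists():
        raise InputError(f"missing required input file: {path}")
    return path


def _load_position(cdir: Path):
    vol = load_volume(_require(cdir / "volume.nii.gz"))
    masks = {
        name: load_mask(_require(cdir / f"{name}.nii.gz"), label_name=name)
        for name in MASK_FILES
    }
    return vol, masks


def _laterality_of(sdir: Path) -> str:
    meta = sdir / "meta.yaml"
    if meta.exists():
        with open(meta) as fh:
            return yaml.safe_load(fh).get("laterality", "right")
    return "right"


def run_subject(config: RunConfig, subject_id: str) -> pd.DataFrame:
    """Process one subject end to end; returns its tidy motion rows.

    Stage order is fixed: rigid tibia alignment, resampling into the
    template frame, deformable registration of the joint meniscus mask,
    cropping with the template per-meniscus masks, arc-length
    partitioning, axis projection.  All artifacts (rigid parameters,
    deformation fields, segment labels, objective traces, motion rows)
    are persisted under ``output_root/subject_id``.
    """
    in_dir = Path(config.input_root) / subject_id
    if not in_dir.exists():
        raise InputError(f"no such subject directory: {in_dir}")
    out_dir = Path(config.output_root) / subject_id
    out_dir.mkdir(parents=True, exist_ok=True)
    laterality = _laterality_of(in_dir)

    t_vol, t_masks = _load_position(in_dir / config.template_condition)
    grid = t_vol.grid
    joint_t = LabelMask(
        t_masks["meniscus_medial"].data | t_masks["meniscus_lateral"].data,
        grid, "meniscus_joint",
    )
    axes = anatomical_axes(
        t_masks["meniscus_medial"], t_masks["meniscus_lateral"], laterality
    )
    seg_labels = {}
    for men_id, key in (("MM", "meniscus_medial"), ("LM", "meniscus_lateral")):
        seg_labels[men_id] = partition_arch(t_masks[key], axes)
        save_mask(
            LabelMask((seg_labels[men_id].data > 0), grid, "segments"),
            out_dir / f"segments_{men_id}_support.nii.gz",
        )
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(seg_labels[men_id].data.astype(np.uint8), grid.affine),
            str(out_dir / f"segments_{men_id}.nii.gz"),
        )

    rows = []
    for condition in config.conditions:
        m_vol, m_masks = _load_position(in_dir / condition)
        logger.info("%s/%s: rigid stage", subject_id, condition)
        rigid = register_rigid(t_vol, m_vol, t_masks["tibia"])
        with open(out_dir / f"rigid_{condition}.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "rotation_rad": [float(x) for x in rigid.rotation],
                    "translation_mm": [float(x) for x in rigid.translation],
                    "center_mm": [float(x) for x in rigid.center],
                },
                fh,
            )
        tr = GridTransform(kind="rigid", payload=rigid, frame=grid)
        aligned = {
            name: resample(m_masks[name], tr, interpolation="nearest")
            for name in ("meniscus_medial", "meniscus_lateral")
        }
        joint_m = LabelMask(
            aligned["meniscus_medial"].data | aligned["meniscus_lateral"].data,
            grid, "meniscus_joint",
        )
        logger.info("%s/%s: deformable stage", subject_id, condition)
        field = register_deformable(
            joint_t, joint_m, config.weights, config.schedule, seed=config.seed
        )
        _save_field(field, out_dir / f"field_{condition}.nii.gz")
        field.trace.to_csv(out_dir / f"trace_{condition}.csv", index=False)

        for men_id, key in (("MM", "meniscus_medial"), ("LM", "meniscus_lateral")):
            crop_field(field, t_masks[key])  # validates grid/mask compatibility
            motions = segment_motion(field, seg_labels[men_id], axes, men_id)
            for sm in motions:
                rows.append(
                    dict(
                        subject=subject_id,
                        laterality=laterality,
                        condition=condition,
                        meniscus=sm.meniscus,
                        segment=sm.segment,
                        avg_mm=round(sm.avg_mm, 6),
                        ml_mm=round(sm.ml_mm, 6),
                        ap_mm=round(sm.ap_mm, 6),
                        n_voxels=sm.n_voxels,
                    )
                )
    df = pd.DataFrame(rows, columns=MOTION_COLUMNS).sort_values(
        ["subject", "condition", "meniscus", "segment"], kind="stable"
    ).reset_index(drop=True)
    df.to_csv(out_dir / "motion.csv", index=False)
    return df


def run_cohort(config: RunConfig, subject_ids: Optional[List[str]] = None):
    """Run every subject, then cohort statistics; returns (motions, summary, comparisons).

    Per-subject failures abort by default; with ``config.allow_partial``
    failing subjects are quarantined (logged and skipped) and the cohort
    proceeds with the remainder.
    """
    from .stats import compare_conditions, summarize

    root = Path(config.input_root)
    if not root.exists():
        raise InputError(f"input root does not exist: {root}")
    out_root = Path(config.output_root)
    out_root.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_root / "config.yaml")
    logger.info("cohort run, config digest %s", config.digest())

    if subject_ids is None:
        subject_ids = [p.name for p in _subject_dirs(root)]
    if len(subject_ids) < 2:
        raise InputError("a cohort run needs at least 2 subjects")

    frames, failed = [], []
    for sid in sorted(subject_ids):
        try:
            frames.append(run_subject(config, sid))
        except Exception as exc:
            if not config.allow_partial:
                raise
            logger.warning("subject %s quarantined: %s", sid, exc)
            failed.append(sid)
    if len(frames) < 2:
        raise PairingError(f"fewer than 2 usable subjects (failed: {failed})")

    motions = pd.concat(frames, ignore_index=True).sort_values(
        ["subject", "condition", "meniscus", "segment"], kind="stable"
    ).reset_index(drop=True)
    motions.to_csv(out_root / "motions.csv", index=False)

    summary = summarize(motions)
    summary.to_csv(out_root / "summary.csv", index=False, float_format="%.6f")
    comparisons = compare_conditions(motions)
    comparisons.to_csv(out_root / "comparisons.csv", index=False, float_format="%.6g")
    write_report(motions, summary, comparisons, out_root)
    return motions, summary, comparisons


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def _fmt_cell(summary: pd.DataFrame, condition, meniscus, segment, measure) -> str:
    q = summary[
        (summary.condition == condition)
        & (summary.meniscus == meniscus)
        & (summary.segment == segment)
        & (summary.measure == measure)
    ]
    if q.empty:
        return "-"
    r = q.iloc[0]
    return f"{r['mean']:.2f} ({r['sd']:.2f})"


def _vector_figure(summary: pd.DataFrame, condition: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes_ = plt.subplots(1, 2, figsize=(8, 4), sharex=True, sharey=True)
    colors = {"AH": "gold", "IH": "red", "PH": "blue", "whole": "black"}
    for ax, men in zip(axes_, ("LM", "MM")):
        for seg in ("AH", "IH", "PH", "whole"):
            ml = summary[(summary.condition == condition) & (summary.meniscus == men)
                         & (summary.segment == seg) & (summary.measure == "ml")]["mean"]
            ap = summary[(summary.condition == condition) & (summary.meniscus == men)
                         & (summary.segment == seg) & (summary.measure == "ap")]["mean"]
            if ml.empty or ap.empty:
                continue
            ax.annotate(
                "", xy=(float(ml.iloc[0]), float(ap.iloc[0])), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color=colors[seg], lw=2),
            )
        ax.axhline(0, color="0.8", lw=0.5)
        ax.axvline(0, color="0.8", lw=0.5)
        ax.set_title(f"{men} ({condition})")
        ax.set_xlabel("ML (mm, + lateral)")
        ax.set_ylabel("AP (mm, + posterior)")
        ax.set_aspect("equal")
        lim = max(1.0, summary[summary.condition == condition]["mean"].abs().max() * 1.3)
        ax.set_xlim(-lim, lim)
        ax.set_ylim(-lim, lim)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_report(motions, summary, comparisons, out_root) -> Path:
    """Markdown report: summary table, comparison grid, vector figures."""
    out_root = Path(out_root)
    conditions = sorted(summary["condition"].unique())
    lines = ["# Meniscal motion cohort report", ""]
    n_subj = motions["subject"].nunique()
    lines.append(f"Subjects: {n_subj}; conditions: {', '.join(conditions)}.")
    lines.append("")
    lines.append("## Mean (SD) motion per meniscus and segment [mm]")
    lines.append("")
    header = "| condition | meniscus | segment | Avg | ML | AP |"
    lines += [header, "|---" * 6 + "|"]
    for condition in conditions:
        for men in ("MM", "LM"):
            for seg in ("whole", "AH", "IH", "PH"):
                lines.append(
                    f"| {condition} | {men} | {seg} | "
                    f"{_fmt_cell(summary, condition, men, seg, 'avg')} | "
                    f"{_fmt_cell(summary, condition, men, seg, 'ml')} | "
                    f"{_fmt_cell(summary, condition, men, seg, 'ap')} |"
                )
    lines.append("")
    lines.append("## Wilcoxon signed-rank comparisons (two-sided p, no multiplicity adjustment)")
    lines.append("")
    lines += ["| family | condition | segment | measure | W+ | p | n | method |",
              "|---" * 8 + "|"]
    for _, r in comparisons.iterrows():
        lines.append(
            f"| {r.family} | {r.condition} | {r.segment} | {r.measure} | "
            f"{r.statistic:.1f} | {r.p_value:.4g} | {r.n_effective} | {r.method} |"
        )
    lines.append("")
    for condition in conditions:
        fig_path = out_root / f"vectors_{condition}.png"
        try:
            _vector_figure(summary, condition, fig_path)
            lines.append(f"![per-segment motion vectors, {condition}]({fig_path.name})")
        except Exception as exc:  # plotting must never sink a cohort run
            logger.warning("figure for %s failed: %s", condition, exc)
    report = out_root / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
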