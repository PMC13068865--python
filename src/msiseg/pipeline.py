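"""End-to-end evaluation: volumes in, per-contour/slice/patient report out.

Per slice the pipeline runs component extraction, optional concave-mask
splitting (both sides by default), nearest-COM pairing, then the MSI and the
traditional metric panel for every pair. Contour MSI values aggregate to a
slice median; slice medians aggregate to the patient mean. Slices with an
ambiguous pairing are flagged and excluded from the aggregates unless
``include_flagged`` is set; their greedy pairing is still evaluated and
reported so a reviewer can act on it. Segmentation-quality problems are
data (flags), never errors — only I/O and volume incompatibility abort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contour_ops import (
    Mask2D,
    SplitParams,
    connected_components,
    mask_to_contour,
    split_concave_mask,
)
from .mask_io import MaskVolume, SlicePair, iter_slice_pairs, load_mask_volume
from .metrics import compute_panel
from .msi import MSIParams, msi_pair, patient_msi, slice_msi
from .pairing import pair_contours

__all__ = ["PipelineConfig", "MetricReport", "run_evaluation", "evaluate_volumes",
           "write_report", "read_report", "render_overlay"]

logger = logging.getLogger(__name__)

_REF_COLORS = ("purple", "green", "gold", "blue")  # reference contour palette


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    ref_path: str | None = None
    test_path: str | None = None
    label: int = 1
    slice_axis: int = 2
    msi: MSIParams = field(default_factory=MSIParams)
    split: SplitParams = field(default_factory=SplitParams)
    split_enabled: bool = True
    split_ref: bool = True
    split_test: bool = True
    surface_dice_tol_mm: float = 3.0
    apl_tol_px: float = 0.0
    include_flagged: bool = False
    overlays: bool = False
    output_dir: str | None = None
    log_level: str = "INFO"

    def snapshot(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if isinstance(data.get("msi"), dict):
            data["msi"] = MSIParams(**data["msi"])
        if isinstance(data.get("split"), dict):
            data["split"] = SplitParams(**data["split"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class MetricReport:
    """Per-contour, per-slice and patient-level results plus run metadata.

    ``contours`` has one row per evaluated (reference, test) pair;
    ``slices`` one row per slice; ``patient`` the aggregate summary. Patient
    values are recomputable from the slice rows, slice values from the
    contour rows (aggregate-consistency invariant, tested).
    """

    contours: pd.DataFrame
    slices: pd.DataFrame
    patient: dict
    flags: list[str]
    config: dict


def _components(slice_mask: np.ndarray, cfg: PipelineConfig, side: str) -> list[Mask2D]:
    comps = connected_components(slice_mask)
    do_split = cfg.split_enabled and (cfg.split_ref if side == "ref" else cfg.split_test)
    if not do_split:
        return comps
    out: list[Mask2D] = []
    for c in comps:
        out.extend(split_concave_mask(c, cfg.split))
    return out


def evaluate_volumes(
    ref: MaskVolume,
    test: MaskVolume,
    config: PipelineConfig | None = None,
) -> MetricReport:
    """Evaluate a test volume against a reference, slice by slice."""
    cfg = config or PipelineConfig()
    contour_rows: list[dict] = []
    slice_rows: list[dict] = []
    flag_lines: list[str] = []
    overlay_jobs: list[tuple[SlicePair, list, list, object, list]] = []

    for pair in iter_slice_pairs(ref, test):
        if pair.skippable:
            slice_rows.append({
                "slice": pair.index, "n_ref": 0, "n_test": 0,
                "msi_median": np.nan, "flagged": False, "flags": "empty",
            })
            continue
        refs = _components(pair.ref, cfg, "ref")
        tests = _components(pair.test, cfg, "test")
        pairing = pair_contours(refs, tests)
        slice_flags = list(pairing.reasons)
        for side, comps in (("ref", refs), ("test", tests)):
            for k, m in enumerate(comps):
                for fl in m.flags:
                    slice_flags.append(f"{side} contour {k}: {fl}")
        if pairing.ambiguous:
            flag_lines.append(
                f"slice={pair.index} refs={len(refs)} tests={len(tests)} "
                f"reason={'; '.join(pairing.reasons)}"
            )
        scores = []
        for ri, ti in pairing.pairs:
            ref_mask, test_mask = refs[ri], tests[ti]
            ref_c = mask_to_contour(ref_mask)
            test_c = mask_to_contour(test_mask)
            score = msi_pair(test_c, ref_c, ref_mask, cfg.msi, spacing=pair.spacing)
            panel = compute_panel(
                ref_mask, test_mask, spacing=pair.spacing,
                surface_dice_tol_mm=cfg.surface_dice_tol_mm,
                apl_tol_px=cfg.apl_tol_px,
                ref_contour=ref_c, test_contour=test_c,
            )
            scores.append(score)
            contour_rows.append({
                "slice": pair.index, "ref_contour": ri, "test_contour": ti,
                "msi": score.value, "n_points": score.n_points,
                "dice": panel.dice, "jaccard": panel.jaccard,
                "avg_hausdorff_mm": panel.avg_hausdorff_mm,
                "hd95_mm": panel.hd95_mm, "hausdorff_mm": panel.hausdorff_mm,
                "surface_dice": panel.surface_dice, "apl_px": panel.apl_px,
                "slice_flagged": pairing.ambiguous,
                "flags": ";".join(score.flags + panel.flags),
            })
        median = slice_msi(scores) if scores else None
        slice_rows.append({
            "slice": pair.index, "n_ref": len(refs), "n_test": len(tests),
            "msi_median": np.nan if median is None else median,
            "flagged": pairing.ambiguous,
            "flags": ";".join(slice_flags),
        })
        if cfg.overlays and cfg.output_dir:
            overlay_jobs.append((pair, refs, tests, pairing, scores))

    contours_df = pd.DataFrame(contour_rows, columns=[
        "slice", "ref_contour", "test_contour", "msi", "n_points", "dice",
        "jaccard", "avg_hausdorff_mm", "hd95_mm", "hausdorff_mm",
        "surface_dice", "apl_px", "slice_flagged", "flags",
    ])
    slices_df = pd.DataFrame(slice_rows, columns=[
        "slice", "n_ref", "n_test", "msi_median", "flagged", "flags",
    ])

    usable = slices_df[~slices_df["msi_median"].isna()]
    if not cfg.include_flagged:
        usable = usable[~usable["flagged"]]
    pm = patient_msi(list(usable["msi_median"]))
    crows = contours_df
    if not cfg.include_flagged and len(crows):
        crows = crows[~crows["slice_flagged"]]
    metric_means = {
        col: (float(crows[col].mean()) if len(crows) else None)
        for col in ("msi", "dice", "jaccard", "avg_hausdorff_mm", "hd95_mm",
                    "hausdorff_mm", "surface_dice", "apl_px")
    }
    patient = {
        "patient_msi": pm,
        "n_slices": int(len(slices_df)),
        "n_slices_evaluated": int(len(usable)),
        "n_slices_flagged": int(slices_df["flagged"].sum()) if len(slices_df) else 0,
        "metric_means": metric_means,
    }
    report = MetricReport(
        contours=contours_df,
        slices=slices_df,
        patient=patient,
        flags=flag_lines,
        config=cfg.snapshot(),
    )
    for job in overlay_jobs:
        try:
            spair, refs, tests, pairing, scores = job
            out = Path(cfg.output_dir) / "overlays" / f"slice_{spair.index:03d}.png"
            render_overlay(spair, refs, tests, pairing, scores, out)
        except Exception as exc:  # rendering must never kill a run
            logger.warning("overlay for slice %d failed: %s", job[0].index, exc)
    return report


def run_evaluation(config: PipelineConfig) -> MetricReport:
    """Load the configured volumes and evaluate them."""
    if not config.ref_path or not config.test_path:
        raise ValueError("config must set ref_path and test_path")
    ref = load_mask_volume(config.ref_path, config.label, config.slice_axis)
    test = load_mask_volume(config.test_path, config.label, config.slice_axis)
    return evaluate_volumes(ref, test, config)


def write_report(report: MetricReport, output_dir: str | Path) -> dict[str, Path]:
    """Write contours.csv, slices.csv, patient.json and flags.log.

    Output is deterministic: repeated runs on identical input produce
    byte-identical files (no timestamps outside metadata).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "contours": out / "contours.csv",
        "slices": out / "slices.csv",
        "patient": out / "patient.json",
        "flags": out / "flags.log",
    }
    report.contours.to_csv(paths["contours"], index=False)
    report.slices.to_csv(paths["slices"], index=False)
    summary = {
        "patient": report.patient,
        "config": report.config,
        "conventions": {
            "connectivity": 8,
            "contour": "outer boundary pixels, Moore trace",
            "hd95": "max of directed 95th percentiles, linear interpolation",
            "surface_dice": "pooled both directions",
            "apl": "reference boundary pixels unmatched, px",
        },
        "version": __version__,
    }
    paths["patient"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    paths["flags"].write_text("".join(line + "\n" for line in report.flags))
    return paths


def read_report(output_dir: str | Path) -> MetricReport:
    """Parse a written report back (round-trip of :func:`write_report`)."""
    out = Path(output_dir)
    contours = pd.read_csv(out / "contours.csv")
    slices = pd.read_csv(out / "slices.csv")
    summary = json.loads((out / "patient.json").read_text())
    flags = [ln for ln in (out / "flags.log").read_text().splitlines() if ln]
    return MetricReport(
        contours=contours,
        slices=slices,
        patient=summary["patient"],
        flags=flags,
        config=summary["config"],
    )


def render_overlay(
    slice_pair: SlicePair,
    refs: list[Mask2D],
    tests: list[Mask2D],
    pairing,
    scores,
    out_path: str | Path,
) -> Path:
    """Save a per-slice figure: reference contours in distinct colors, test
    contours in red, per-pair MSI annotated; flagged slices are marked for
    manual review."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(np.zeros_like(slice_pair.ref, dtype=float), cmap="gray", vmin=0, vmax=1)
    for k, m in enumerate(refs):
        c = mask_to_contour(m)
        pts = np.vstack([c.points, c.points[:1]]) if c.closed else c.points
        ax.plot(pts[:, 1], pts[:, 0], color=_REF_COLORS[k % len(_REF_COLORS)],
                lw=1.5, label=f"ref {k}")
    for m in tests:
        c = mask_to_contour(m)
        pts = np.vstack([c.points, c.points[:1]]) if c.closed else c.points
        ax.plot(pts[:, 1], pts[:, 0], color="red", lw=1.2)
    for (ri, ti), score in zip(pairing.pairs, scores):
        com = refs[ri].com
        ax.annotate(f"MSI {score.value:.2f}", (com[1], com[0]),
                    color="white", fontsize=8, ha="center")
    title = f"slice {slice_pair.index}"
    if pairing.ambiguous:
        title += "  [FLAGGED: manual review]"
    ax.set_title(title, fontsize=10)
    ax.legend(loc="lower right", fontsize=7)
    ax.set_axis_off()
    fig.savefig(out_path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return out_path
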