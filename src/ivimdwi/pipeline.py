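"""End-to-end orchestration: simulate -> fit -> stats.

Each stage reads and writes plain files (NIfTI stacks, bval lists, CSV
tables, JSON summaries) so stages are independently runnable, resumable
and scriptable.  A single master seed makes the whole pipeline
deterministic; every output directory carries a manifest recording the
seed and a hash of the configuration.
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

from .fitting import FitConfig, fit_volume
from .io import read_dwi_stack, write_dwi_stack, write_parameter_maps
from .phantom import CohortSpec, default_phantom_spec, simulate_cohort
from .roi import extract_roi_means, oval_roi_for_label, roi_from_label
from .stats import friedman_report, table2_report, table3_report, table4_report

logger = logging.getLogger("ivimdwi")

__all__ = ["RunConfig", "run_simulate", "run_fit", "run_stats", "run_all"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input_dir`` points at existing stacks (dwi + bval + labels per
    subject) or a synthetic cohort is generated from ``cohort``; not
    neither.  ``roi_only`` restricts the voxel-wise fits to a box around
    each subject's ROI — the maps still cover the full grid, with
    out-of-box voxels flagged as skipped — which is the honest shortcut
    when only ROI means are consumed downstream.
    """

    out_dir: str = "ivimdwi_out"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    snr_b0: float | None = 40.0
    input_dir: str | None = None
    roi_only: bool = False
    skip_existing: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "cohort": dataclasses.asdict(self.cohort),
                "fit": dataclasses.asdict(self.fit),
                "snr_b0": self.snr_b0,
                "roi_only": self.roi_only,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_manifest(path: Path, config: RunConfig, extra: dict) -> None:
    manifest = {"seed": config.seed, "config_hash": config.config_hash(), **extra}
    path.write_text(json.dumps(manifest, indent=2, default=str))


def run_simulate(config: RunConfig) -> Path:
    """Generate the synthetic cohort: per-subject stacks, labels, truth table.

    Deterministic per seed; re-running with the same seed rewrites
    byte-identical truth tables.
    """
    out = Path(config.out_dir)
    stacks_dir = out / "stacks"
    stacks_dir.mkdir(parents=True, exist_ok=True)
    cohort = dataclasses.replace(config.cohort, seed=config.seed)
    template = default_phantom_spec(snr_b0=config.snr_b0, seed=config.seed)
    table, stacks = simulate_cohort(cohort, template=template, seed=config.seed)
    import nibabel as nib

    for sid, (stack, labels) in stacks.items():
        write_dwi_stack(stack, stacks_dir / f"{sid}_dwi.nii.gz", stacks_dir / f"{sid}.bval")
        aff = np.diag([*stack.spacing, 1.0])
        nib.save(
            nib.Nifti1Image(labels.astype(np.int16), aff),
            str(stacks_dir / f"{sid}_labels.nii.gz"),
        )
        logger.info("simulated %s", sid)
    truth_path = out / "truth.csv"
    table.to_csv(truth_path, index=False, float_format="%.10g")
    _write_manifest(
        out / "simulate_manifest.json", config,
        {"n_subjects": len(table), "subjects": sorted(stacks)},
    )
    return truth_path


def _subject_roi(labels: np.ndarray, group: str, spacing):
    """Study-protocol ROI: an oval on the lesion for cancer subjects, a
    smaller oval inside the gland for healthy subjects."""
    if group == "cancer":
        return oval_roi_for_label(labels, 2, spacing)
    return oval_roi_for_label(labels, 1, spacing, max_semi_axes_mm=(5.0, 4.0))


def _roi_box_mask(roi_mask: np.ndarray, pad: int = 1) -> np.ndarray:
    box = np.zeros_like(roi_mask)
    idx = np.nonzero(roi_mask)
    lo = [max(int(a.min()) - pad, 0) for a in idx]
    hi = [int(a.max()) + pad + 1 for a in idx]
    box[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return box


def run_fit(config: RunConfig) -> Path:
    """Fit every simulated (or provided) subject and extract ROI means.

    Resumable: subjects whose map directory already exists are skipped when
    ``skip_existing`` is set.  A subject whose stack cannot be processed is
    logged and skipped; the run completes with a partial-failure marker in
    the manifest rather than aborting.
    """
    import nibabel as nib

    out = Path(config.out_dir)
    stacks_dir = Path(config.input_dir) if config.input_dir else out / "stacks"
    truth = pd.read_csv(out / "truth.csv") if (out / "truth.csv").exists() else None
    maps_dir = out / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)

    rows, failures = [], []
    for dwi_path in sorted(stacks_dir.glob("*_dwi.nii.gz")):
        sid = dwi_path.name.replace("_dwi.nii.gz", "")
        subj_dir = maps_dir / sid
        row_cache = subj_dir / "roi_means.json"
        if config.skip_existing and row_cache.exists():
            rows.append(json.loads(row_cache.read_text()))
            logger.info("%s: cached", sid)
            continue
        try:
            stack = read_dwi_stack(dwi_path, stacks_dir / f"{sid}.bval")
            labels = np.asarray(
                nib.load(str(stacks_dir / f"{sid}_labels.nii.gz")).get_fdata()
            ).astype(int)
            if truth is not None and sid in set(truth["subject_id"]):
                group = truth.loc[truth["subject_id"] == sid, "group"].iloc[0]
            else:
                group = "cancer" if (labels == 2).any() else "healthy"
            roi = _subject_roi(labels, group, stack.spacing)
            if config.roi_only:
                keep = _roi_box_mask(roi.mask)
                data = stack.data.copy()
                data[~keep] = 0.0  # flagged BACKGROUND, never fitted
                stack = dataclasses.replace(stack, data=data)
            maps = fit_volume(stack, config.fit)
            write_parameter_maps(maps, subj_dir, affine=stack.affine, spacing=stack.spacing)
            means, excluded = extract_roi_means(maps, roi)
            row = {
                "subject_id": sid,
                "group": group,
                "roi_area_mm2": roi.area_mm2,
                "excluded_fraction": excluded,
                **means,
            }
            if truth is not None and sid in set(truth["subject_id"]):
                trow = truth.loc[truth["subject_id"] == sid].iloc[0]
                for attr in ("grade", "location", "t_stage", "nodal", "size_mm"):
                    if attr in truth.columns:
                        row[attr] = trow[attr]
            subj_dir.mkdir(parents=True, exist_ok=True)
            row_cache.write_text(json.dumps(row, default=str))
            rows.append(row)
            logger.info("%s: fitted", sid)
        except Exception as exc:  # per-subject isolation
            failures.append({"subject": sid, "error": str(exc)})
            logger.error("%s: FAILED (%s)", sid, exc)
    if not rows:
        raise RuntimeError("no subject produced ROI means")
    table = pd.DataFrame(rows)
    table_path = out / "subjects.csv"
    table.to_csv(table_path, index=False, float_format="%.10g")
    _write_manifest(
        out / "fit_manifest.json", config,
        {"n_fitted": len(rows), "failures": failures},
    )
    return table_path


def run_stats(config: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Produce the report battery from the subject table.

    Writes table2/3/4-shaped CSVs, the Friedman + post-hoc report, and a
    machine-readable JSON summary.  With a single-group table the
    between-group reports are skipped with a warning; the within-cancer
    strata table still runs when attributes are present.
    """
    out = Path(config.out_dir)
    if table is None:
        table = pd.read_csv(out / "subjects.csv")
    out.mkdir(parents=True, exist_ok=True)
    groups = set(table["group"].unique())
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    if {"cancer", "healthy"} <= groups:
        t2 = table2_report(table)
        t2.to_csv(out / "table2_group_comparison.csv", index=False)
        t3 = table3_report(table)
        t3.to_csv(out / "table3_roc.csv", index=False)
        summary["group_comparison"] = t2.to_dict(orient="records")
        summary["roc"] = t3.to_dict(orient="records")
        fried = {}
        for grp in ("cancer", "healthy"):
            fr, family = friedman_report(table, grp)
            fried[grp] = {
                "statistic": fr.statistic,
                "p_value": fr.p_value,
                "n_pairs": family.n_pairs,
                "corrected_threshold": family.corrected_threshold,
                "n_significant_pairs": len(family.significant_pairs),
            }
        summary["friedman"] = fried
    else:
        logger.warning("single-group table: between-group reports skipped")
        summary["group_comparison"] = None

    if "grade" in table.columns and (table["group"] == "cancer").any():
        t4 = table4_report(table)
        if not t4.empty:
            t4.to_csv(out / "table4_strata.csv", index=False)
            summary["strata"] = t4.to_dict(orient="records")
    (out / "stats_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def run_all(config: RunConfig) -> dict:
    run_simulate(config)
    run_fit(config)
    return run_stats(config)
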