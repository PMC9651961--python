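"""End-to-end orchestration of the phantom experiment.

simulate -> spike detection + task GLM -> source-to-EC semipartial
connectivity -> group T maps -> winner-take-all entorhinal seeds ->
seed-to-hippocampus connectivity -> transversal segmentation and segment
extraction -> hierarchical gradient statistics and content-bias statistics.

Every stage is the library function the corresponding CLI subcommand also
calls, so unit and integration paths cannot diverge.  A pipeline run is a
pure function of (config, seed): rerunning with the same configuration
reproduces every artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import SOURCE_ORDER, PipelineConfig
from .connectivity import (ConnectivityMap, intensity_exclude,
                           mean_timeseries, semipartial_connectivity)
from .exceptions import TransfcError
from .glm import (BoldRun, GlmFit, build_design, contrast, detect_spikes,
                  fit_glm, smooth_run)
from .parcellation import (SeedAssignment, equalize_across_hemispheres,
                           one_sample_tmap, parcellation_accuracy,
                           winner_take_all)
from .phantom import LABELS, PhantomAnatomy, simulate_group
from .segmentation import (TransversalSegmentation, build_estimate_table,
                           extract_segment_profile, segment_roi, write_table)
from .stats import ContentBiasAnalysis, GradientAnalysis

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory summary of one pipeline run."""

    config: PipelineConfig
    assignment: SeedAssignment
    parcellation_accuracy: float
    gradient_tables: Dict[str, pd.DataFrame]
    gradient_report: "stats.GradientResults"
    content_tables: Dict[str, pd.DataFrame]
    content_reports: Dict[str, "stats.ContentResults"]
    seed_counts: Dict[str, int]
    out_dir: Optional[Path] = None
    segmentations: Dict[str, TransversalSegmentation] = field(default_factory=dict)

    def report_dict(self) -> dict:
        return {
            "parcellation_accuracy": self.parcellation_accuracy,
            "seed_counts": self.seed_counts,
            "gradient": self.gradient_report.to_dict(),
            "content": {k: v.to_dict() for k, v in self.content_reports.items()},
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _standardize(series: np.ndarray) -> np.ndarray:
    sd = series.std(axis=-1, keepdims=True)
    return (series - series.mean(axis=-1, keepdims=True)) / np.where(
        sd > 0, sd, 1.0)


def _concat_runs(runs: List[BoldRun]) -> BoldRun:
    """Concatenate runs along time after per-run voxelwise standardization."""
    if len(runs) == 1:
        return runs[0]
    data = np.concatenate([_standardize(r.data) for r in runs], axis=-1)
    return BoldRun(data=data, tr_seconds=runs[0].tr_seconds)


def _subject_nuisance(anatomy: PhantomAnatomy, residual: BoldRun,
                      nuisances, n_time_total: int) -> np.ndarray:
    """Connectivity nuisance matrix: motion, spike one-hots, WM and CSF."""
    motion = np.concatenate([n.motion for n in nuisances], axis=0)
    cols = [motion]
    offset = 0
    for n in nuisances:
        T = n.motion.shape[0]
        for idx in sorted(n.spikes):
            one_hot = np.zeros(n_time_total)
            one_hot[offset + idx] = 1.0
            cols.append(one_hot[:, None])
        offset += T
    wm = mean_timeseries(residual, anatomy.mask("WM"))
    csf = mean_timeseries(residual, anatomy.mask("CSF"))
    cols.append(wm[:, None])
    cols.append(csf[:, None])
    return np.column_stack(cols)


def _seed_to_voxel_maps(residual: BoldRun, seed_masks: Dict[str, np.ndarray],
                        nuisance: np.ndarray, target_mask: np.ndarray,
                        config: PipelineConfig, raw_run: BoldRun,
                        subject_id: str) -> Dict[str, ConnectivityMap]:
    """Semipartial z-map per seed, controls = the other seeds' series."""
    series = {}
    for name, mask in seed_masks.items():
        usable = intensity_exclude(mask, raw_run, config.intensity_k_sd)
        series[name] = mean_timeseries(residual, usable)
    maps = {}
    for name in seed_masks:
        controls = [series[o] for o in seed_masks if o != name]
        maps[name] = semipartial_connectivity(
            residual, series[name], controls, nuisance, config.band_hz,
            mask=target_mask, seed_name=name, subject_id=subject_id)
    return maps


def run_pipeline(config: PipelineConfig, out_dir=None,
                 write_artifacts: bool = True) -> PipelineResult:
    """Run the full phantom experiment and (optionally) write all artifacts."""
    from . import io, stats  # noqa: F401  (io used conditionally below)

    out = Path(out_dir) if out_dir is not None else None
    if write_artifacts and out is None:
        raise TransfcError("write_artifacts=True requires an output directory")
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        anatomy, truth, events, subjects = simulate_group(config.phantom)
        ec_mask = anatomy.mask("EC")
        hip_mask = anatomy.mask("SUB") | anatomy.mask("CA1")
        source_masks = {s: anatomy.mask(s) for s in SOURCE_ORDER}

        if write_artifacts:
            io.save_label_map(anatomy.labels, anatomy.legend, anatomy.axes,
                              out / "labels.nii.gz", config.voxel_size_mm)
            io.save_events_tsv(events[0], out / "events.tsv")
            for subj in subjects:
                for r, (run, nuis) in enumerate(zip(subj.runs, subj.nuisance)):
                    io.save_bold_run(run, out / f"{subj.subject_id}_run-{r + 1}"
                                     "_bold.nii.gz", config.voxel_size_mm)
                    io.save_motion_tsv(nuis.motion,
                                       out / f"{subj.subject_id}_run-{r + 1}"
                                       "_motion.tsv")

        stage = "glm"
        residuals: Dict[str, BoldRun] = {}
        raw_concat: Dict[str, BoldRun] = {}
        contrasts: Dict[str, Dict[str, np.ndarray]] = {}
        nuisance_mats: Dict[str, np.ndarray] = {}
        for subj in subjects:
            resid_runs, fits = [], []
            for run, nuis in zip(subj.runs, subj.nuisance):
                smoothed = smooth_run(run, config.fwhm_mm, config.voxel_size_mm)
                nuis.spikes = detect_spikes(smoothed, nuis.motion,
                                            config.art_intensity_pct,
                                            config.art_motion_mm)
                design = build_design(events[0], nuis, run.n_volumes,
                                      run.tr_seconds)
                fit = fit_glm(smoothed, design)
                resid_runs.append(fit.residual_run)
                fits.append(fit)
            residuals[subj.subject_id] = _concat_runs(resid_runs)
            raw_concat[subj.subject_id] = _concat_runs(subj.runs)
            n_total = residuals[subj.subject_id].n_volumes
            nuisance_mats[subj.subject_id] = _subject_nuisance(
                anatomy, residuals[subj.subject_id], subj.nuisance, n_total)
            scene = _mean_contrast(fits, {"scene": 1.0, "baseline": -1.0},
                                   "scene_gt_baseline")
            objc = _mean_contrast(fits, {"object": 1.0, "baseline": -1.0},
                                  "object_gt_baseline")
            contrasts[subj.subject_id] = {"scene": scene, "object": objc}

        stage = "connect-sources"
        source_zmaps: Dict[str, Dict[str, np.ndarray]] = {s: {} for s in SOURCE_ORDER}
        for subj in subjects:
            maps = _seed_to_voxel_maps(
                residuals[subj.subject_id], source_masks,
                nuisance_mats[subj.subject_id], ec_mask, config,
                raw_concat[subj.subject_id], subj.subject_id)
            for s in SOURCE_ORDER:
                source_zmaps[s][subj.subject_id] = maps[s].z_values

        stage = "parcellate"
        tmaps = {}
        for s in SOURCE_ORDER:
            stack = [np.nan_to_num(source_zmaps[s][subj.subject_id])
                     for subj in subjects]
            tmaps[s] = one_sample_tmap(stack, source_name=s)
        assignment = winner_take_all(tmaps, config.t_threshold, ec_mask)
        # single-hemisphere phantom: equalization runs as identity
        assignment = equalize_across_hemispheres({"right": assignment})["right"]
        accuracy = parcellation_accuracy(assignment, anatomy.ec_sublabel,
                                         ec_mask)
        seed_counts = assignment.counts()
        log.info("parcellation: accuracy %.3f, seed counts %s",
                 accuracy, seed_counts)
        empty = [s for s, c in seed_counts.items() if c == 0]
        if empty:
            raise TransfcError(f"winner-take-all produced empty seeds: {empty}")
        seed_masks = {f"EC_{s}": assignment.mask(s) for s in SOURCE_ORDER}

        if write_artifacts:
            for s in SOURCE_ORDER:
                io.save_nifti(tmaps[s].t_values.astype(np.float32),
                              out / f"tmap_{s}.nii.gz", config.voxel_size_mm)
            io.save_label_map(assignment.labels,
                              {i + 1: s for i, s in enumerate(SOURCE_ORDER)},
                              anatomy.axes, out / "ec_seeds.nii.gz",
                              config.voxel_size_mm)
            io.save_json({"seed_counts": seed_counts,
                          "parcellation_accuracy": accuracy},
                         out / "parcellation.json")

        stage = "connect-seeds"
        seed_zmaps: Dict[str, Dict[str, Dict[str, np.ndarray]]] = {}
        for subj in subjects:
            maps = _seed_to_voxel_maps(
                residuals[subj.subject_id], seed_masks,
                nuisance_mats[subj.subject_id], hip_mask, config,
                raw_concat[subj.subject_id], subj.subject_id)
            seed_zmaps[subj.subject_id] = {
                name: np.nan_to_num(m.z_values) for name, m in maps.items()}
            if write_artifacts:
                for name, m in maps.items():
                    io.save_nifti(np.nan_to_num(m.z_values).astype(np.float32),
                                  out / f"{subj.subject_id}_{name}_z.nii.gz",
                                  config.voxel_size_mm)

        stage = "segment"
        segmentations = {
            "SUB": segment_roi(anatomy.labels, LABELS["SUB"], anatomy.axes,
                               "bins", n_segments=config.n_sub_segments,
                               roi_name="SUB"),
            "CA1": segment_roi(anatomy.labels, LABELS["CA1"], anatomy.axes,
                               "sectors", angle_deg=config.ca1_angle_deg,
                               roi_name="CA1"),
        }

        stage = "extract"
        gradient_tables = {}
        for region, seg in segmentations.items():
            gradient_tables[region] = build_estimate_table(
                seed_zmaps, seg, voxel_weighted=config.voxel_weighted_slices)
        content_tables = {}
        for region, seg in segmentations.items():
            rows = []
            for subj in subjects:
                for cond in ("scene", "object"):
                    profile = extract_segment_profile(
                        contrasts[subj.subject_id][cond], seg,
                        config.voxel_weighted_slices)
                    for s, val in enumerate(profile, start=1):
                        rows.append((subj.subject_id, cond, s, val))
            content_tables[region] = pd.DataFrame(
                rows, columns=["subject", "condition", "segment", "value"])
        rows = []
        for subj in subjects:
            for cond in ("scene", "object"):
                cmap = contrasts[subj.subject_id][cond]
                for name, mask in seed_masks.items():
                    rows.append((subj.subject_id, cond, name,
                                 float(cmap[mask].mean())))
        content_tables["EC"] = pd.DataFrame(
            rows, columns=["subject", "condition", "region", "value"])

        if write_artifacts:
            for region, seg in segmentations.items():
                io.save_label_map(seg.segments, {}, anatomy.axes,
                                  out / f"seg_{region}.nii.gz",
                                  config.voxel_size_mm)
            for region, table in gradient_tables.items():
                write_table(table, out / f"connectivity_{region}.tsv")
            for region, table in content_tables.items():
                write_table(table, out / f"content_{region}.tsv")

        stage = "stats"
        gradient_report = GradientAnalysis(gradient_tables,
                                           q=config.fdr_q).fit()
        content_reports = {}
        for region, table in content_tables.items():
            unit_col = "region" if region == "EC" else "segment"
            content_reports[region] = ContentBiasAnalysis(
                table, unit_col=unit_col, q=config.fdr_q).fit()

        result = PipelineResult(
            config=config, assignment=assignment,
            parcellation_accuracy=accuracy,
            gradient_tables=gradient_tables, gradient_report=gradient_report,
            content_tables=content_tables, content_reports=content_reports,
            seed_counts=seed_counts, out_dir=out,
            segmentations=segmentations)

        if out is not None:
            io.save_json(result.report_dict(), out / "report.json")
            io.save_json({"config": config.to_dict(),
                          "config_hash": _config_hash(config),
                          "seed": config.phantom.rng_seed,
                          "version": __version__,
                          "numpy": np.__version__},
                         out / "provenance.json")
        return result
    except TransfcError:
        raise
    except Exception as exc:  # annotate internal failures with the stage
        raise TransfcError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _mean_contrast(fits: List[GlmFit], weights: Dict[str, float],
                   name: str) -> np.ndarray:
    maps = [contrast(f, weights, name).values for f in fits]
    return np.mean(maps, axis=0)
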