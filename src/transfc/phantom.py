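"""Synthetic group datasets with known connectivity gradients and content bias.

The phantom emulates the study design end to end: four cortical source
regions (RSC, PHC, A35, A36) each emit one band-limited latent signal; the
entorhinal cortex (EC) contains four hidden subregions, each driven by
exactly one source; subiculum (SUB) and CA1 sheets mix the latents with
weights that vary linearly along a transversal (proximal-to-distal)
coordinate; scene/object/baseline task responses are added with a scene
bias confined to the PHC-driven EC subregion and the distal subiculum.
White noise, synthetic motion traces and global-intensity spike artifacts
complete the simulation, so every downstream stage (GLM, connectivity,
parcellation, segmentation, statistics) is testable against ground truth.

Geometry conventions (recorded in :class:`PhantomAnatomy.axes` so the
segmentation stage never guesses): axis 0 runs medial-to-lateral, axis 1 is
the "coronal" (longitudinal) axis, axis 2 inferior-to-superior.  The
subiculum's proximal end (adjacent to CA1) sits at the lateral edge; CA1's
proximal end at the medial edge of its arc.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import CONDITIONS, SOURCE_ORDER, PhantomConfig
from .exceptions import InvalidConfigError
from .glm import BoldRun, NuisanceSet, convolve_events

#: integer labels of the ROI map
LABELS = {"RSC": 1, "PHC": 2, "A35": 3, "A36": 4,
          "EC": 5, "SUB": 6, "CA1": 7, "WM": 8, "CSF": 9}
LEGEND = {v: k for k, v in LABELS.items()}

#: fraction of the run-mean intensity added to a spiked volume (the 1.3%
#: detection threshold is exceeded by design)
SPIKE_FRACTION = 0.03

#: transversal cut above which the "distal" condition amplitude applies
DISTAL_CUT = 0.6


def flat_gradient_weights(value: float = 0.45) -> dict:
    """Null-hypothesis gradient weights: identical at both transversal ends.

    Useful for type-I-error simulations — no seed differs across segments.
    """
    return {target: {source: (value, value) for source in SOURCE_ORDER}
            for target in ("SUB", "CA1")}


def flat_condition_amplitudes(task: float = 0.5, baseline: float = 0.2) -> dict:
    """Null-hypothesis task amplitudes: no scene/object bias anywhere."""
    amps = {}
    for region in ("EC_RSC", "EC_PHC", "EC_A35", "EC_A36",
                   "SUB_proximal", "SUB_distal", "CA1_proximal", "CA1_distal"):
        amps[(region, "scene")] = task
        amps[(region, "object")] = task
        amps[(region, "baseline")] = baseline
    return amps


@dataclass
class PhantomAnatomy:
    """Label map plus geometric metadata shared by the whole group."""

    labels: np.ndarray                      # 3D int
    legend: Dict[int, str]
    axes: Dict[str, object]                 # coronal_axis, medlat_axis, ...
    ec_sublabel: np.ndarray                 # 3D int, 1..4 inside EC, 0 outside
    transversal_position: np.ndarray        # 3D float, NaN outside SUB/CA1

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


@dataclass
class GroundTruth:
    """Everything the simulation knows that the analysis must recover."""

    voxel_weights: np.ndarray               # n_sources x grid
    transversal_position: np.ndarray        # alias of anatomy array
    ec_sublabel: np.ndarray
    condition_amplitude_maps: Dict[str, np.ndarray]   # condition -> 3D map
    latent_signals: Dict[str, List[np.ndarray]] = field(default_factory=dict)
    # latent_signals[subject_id][run] -> n_sources x time, filled on synthesis


@dataclass
class SubjectData:
    subject_id: str
    runs: List[BoldRun]
    nuisance: List[NuisanceSet]
    latents: List[np.ndarray]               # per run, n_sources x time


def make_latent_sources(n_time: int, tr: float, band: Tuple[float, float],
                        seed: int, n_sources: int = 4) -> np.ndarray:
    """Band-limited standardized Gaussian latent signals (sources x time).

    White Gaussian series are band-limited by zeroing FFT coefficients
    outside ``band`` (DC always removed), then standardized to zero mean
    and unit variance — simple, deterministic, and spectrum-exact.
    """
    low, high = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < low < high < nyquist):
        raise InvalidConfigError(
            f"band {band} invalid for TR {tr} (Nyquist {nyquist:.4f} Hz)")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_sources, n_time))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_time, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    keep[0] = False
    spectrum[:, ~keep] = 0.0
    series = np.fft.irfft(spectrum, n=n_time, axis=1)
    series -= series.mean(axis=1, keepdims=True)
    series /= series.std(axis=1, keepdims=True)
    return series


def build_phantom_anatomy(config: PhantomConfig) -> Tuple[PhantomAnatomy, GroundTruth]:
    """Place all ROIs disjointly on the grid and derive ground-truth maps."""
    nx, ny, nz = config.grid_dims
    if nx < 22 or ny < 20 or nz < 12:
        raise InvalidConfigError(
            f"grid {config.grid_dims} too small to place all ROIs "
            "disjointly; need at least (22, 20, 12)")
    labels = np.zeros(config.grid_dims, dtype=np.int16)
    ec_sub = np.zeros(config.grid_dims, dtype=np.int16)
    tpos = np.full(config.grid_dims, np.nan)

    # cortical sources: four 3x4x3 blocks on coronal slices 1..4
    ys = slice(1, 5)
    source_boxes = {"RSC": (slice(1, 4), ys, slice(1, 4)),
                    "PHC": (slice(1, 4), ys, slice(7, 10)),
                    "A35": (slice(18, 21), ys, slice(1, 4)),
                    "A36": (slice(18, 21), ys, slice(7, 10))}
    for name, box in source_boxes.items():
        labels[box] = LABELS[name]

    # EC: 8 medial-lateral columns x 4 coronal slices x 4 z-planes, hidden
    # 4-way partition into source-driven sublabels along the medlat axis
    ec_box = (slice(8, 16), slice(6, 10), slice(2, 6))
    labels[ec_box] = LABELS["EC"]
    for k, _source in enumerate(SOURCE_ORDER, start=1):
        ec_sub[slice(8 + 2 * (k - 1), 8 + 2 * k), ec_box[1], ec_box[2]] = k

    # hippocampal body: 8 coronal slices
    body = range(12, 20)
    # SUB: 10-voxel-wide sheet at z=3; proximal (t=0) at the lateral end
    sub_x = np.arange(4, 14)
    for y in body:
        labels[sub_x, y, 3] = LABELS["SUB"]
        tpos[sub_x, y, 3] = (sub_x.max() - sub_x) / (sub_x.max() - sub_x.min())
    # CA1: 9-voxel arc per slice around (8, 6) with radius 5; proximal
    # (t=0) at the medial end (theta=170deg), distal adjacent to SUB
    thetas = np.deg2rad(np.arange(10, 171, 20))
    arc_x = np.round(8 + 5 * np.cos(thetas)).astype(int)
    arc_z = np.round(6 + 5 * np.sin(thetas)).astype(int)
    arc_t = (170 - np.rad2deg(thetas)) / 160.0
    for y in body:
        for x, z, t in zip(arc_x, arc_z, arc_t):
            labels[x, y, z] = LABELS["CA1"]
            tpos[x, y, z] = t

    # nuisance tissue blocks
    labels[18:21, 12:20, 1:3] = LABELS["WM"]
    labels[18:21, 12:20, 8:10] = LABELS["CSF"]

    # disjointness is by construction; verify to fail loudly on edits
    placed = sum(int((labels == v).sum()) for v in LEGEND)
    if placed != int((labels > 0).sum()):
        raise InvalidConfigError("ROI placement produced overlapping labels")

    axes = {"coronal_axis": 1, "medlat_axis": 0, "infsup_axis": 2,
            "proximal_lateral": {"SUB": True, "CA1": False}}
    anatomy = PhantomAnatomy(labels=labels, legend=dict(LEGEND), axes=axes,
                             ec_sublabel=ec_sub, transversal_position=tpos)

    weights = _voxel_weights(anatomy, config)
    amp_maps = _amplitude_maps(anatomy, config)
    truth = GroundTruth(voxel_weights=weights, transversal_position=tpos,
                        ec_sublabel=ec_sub,
                        condition_amplitude_maps=amp_maps)
    return anatomy, truth


def _voxel_weights(anatomy: PhantomAnatomy, config: PhantomConfig) -> np.ndarray:
    """n_sources x grid weight array mapping latents onto voxels."""
    w = np.zeros((len(SOURCE_ORDER),) + anatomy.labels.shape)
    for k, source in enumerate(SOURCE_ORDER):
        w[k][anatomy.mask(source)] = 1.0
        w[k][anatomy.ec_sublabel == k + 1] = 1.0
    for target in ("SUB", "CA1"):
        mask = anatomy.mask(target)
        t = anatomy.transversal_position[mask]
        for k, source in enumerate(SOURCE_ORDER):
            prox, dist = config.gradient_weights[target][source]
            w[k][mask] = prox + (dist - prox) * t
    return w


def _amplitude_maps(anatomy: PhantomAnatomy,
                    config: PhantomConfig) -> Dict[str, np.ndarray]:
    """condition -> 3D amplitude map from the (region, condition) table."""
    amps = config.condition_amplitudes
    maps = {}
    for cond in CONDITIONS:
        a = np.zeros(anatomy.labels.shape)
        for k, source in enumerate(SOURCE_ORDER):
            key = (f"EC_{source}", cond)
            if key in amps:
                a[anatomy.ec_sublabel == k + 1] = amps[key]
        for target in ("SUB", "CA1"):
            mask = anatomy.mask(target)
            t = anatomy.transversal_position[mask]
            prox = amps.get((f"{target}_proximal", cond), 0.0)
            dist = amps.get((f"{target}_distal", cond), 0.0)
            # task amplitudes are compartmental, not graded: the distal
            # amplitude applies to the distal portion (t > DISTAL_CUT)
            # only, so a content bias stays confined to distal segments
            a[mask] = np.where(t > DISTAL_CUT, dist, prox)
        for source in SOURCE_ORDER:
            key = (source, cond)
            if key in amps:
                a[anatomy.mask(source)] = amps[key]
        maps[cond] = a
    return maps


def make_event_table(config: PhantomConfig,
                     n_task_blocks: Optional[int] = None,
                     stimulus_s: float = 3.0,
                     block_gap_s: float = 4.8,
                     baseline_stimuli: int = 10) -> pd.DataFrame:
    """Event table for one run: onset, duration, condition.

    Ten 3-s baseline (scrambled) stimuli open and close the run; in
    between, scene and object mini-blocks of two 3-s stimuli alternate,
    separated by ``block_gap_s``.  ``n_task_blocks=None`` fills the run.
    """
    run_s = config.n_volumes_per_run * config.tr_seconds
    base_dur = baseline_stimuli * stimulus_s
    block_dur = 2 * stimulus_s
    avail = run_s - 2 * base_dur
    max_blocks = max(0, int((avail + block_gap_s) // (block_dur + block_gap_s)))
    if n_task_blocks is None:
        n_task_blocks = max_blocks
    if n_task_blocks > max_blocks or avail < 0:
        raise InvalidConfigError(
            f"{n_task_blocks} task blocks do not fit in a {run_s:.0f}-s run")
    rows = []
    t = 0.0
    for _ in range(baseline_stimuli):
        rows.append((t, stimulus_s, "baseline"))
        t += stimulus_s
    for b in range(n_task_blocks):
        cond = "scene" if b % 2 == 0 else "object"
        for _ in range(2):
            rows.append((t, stimulus_s, cond))
            t += stimulus_s
        t += block_gap_s
    t = run_s - base_dur
    for _ in range(baseline_stimuli):
        rows.append((t, stimulus_s, "baseline"))
        t += stimulus_s
    events = pd.DataFrame(rows, columns=["onset", "duration", "condition"])
    events = events.sort_values("onset", kind="stable").reset_index(drop=True)
    onsets = events["onset"].to_numpy()
    if not np.all(np.diff(onsets) > 0):
        raise InvalidConfigError("event onsets are not strictly increasing")
    if np.any(onsets + events["duration"].to_numpy() > run_s + 1e-9):
        raise InvalidConfigError("an event extends past the end of the run")
    return events


def _condition_regressors(events: Optional[pd.DataFrame], n_time: int,
                          tr: float) -> Dict[str, np.ndarray]:
    if events is None or not len(events):
        return {}
    out = {}
    for cond in CONDITIONS:
        sel = events[events["condition"] == cond]
        if len(sel):
            out[cond] = convolve_events(sel["onset"].to_numpy(),
                                        sel["duration"].to_numpy(), n_time, tr)
    return out


def synthesize_subject(anatomy: PhantomAnatomy, truth: GroundTruth,
                       events: Optional[pd.DataFrame], config: PhantomConfig,
                       subject_seed: int,
                       subject_id: str = "sub-00") -> SubjectData:
    """Simulate all runs of one subject.

    Voxel signal = baseline intensity + sum_k weight_k * latent_k
    + HRF-convolved condition regressors scaled by the region amplitude
    + white noise (``noise_sd``) + global-intensity spikes at
    ``spike_rate``.  The returned nuisance sets carry 6 synthetic motion
    columns and the true spike indices.
    """
    n_time = config.n_volumes_per_run
    rng = np.random.default_rng(subject_seed)
    runs, nuisances, latents_out = [], [], []
    regs = _condition_regressors(events, n_time, config.tr_seconds)
    for run_idx in range(config.n_runs):
        latent_seed = int(rng.integers(0, 2**31 - 1))
        latents = make_latent_sources(n_time, config.tr_seconds,
                                      config.band_hz, latent_seed)
        data = np.full(anatomy.labels.shape + (n_time,),
                       config.baseline_intensity)
        data += np.tensordot(truth.voxel_weights, latents, axes=(0, 0))
        for cond, reg in regs.items():
            amp = truth.condition_amplitude_maps[cond]
            data += amp[..., None] * reg[None, None, None, :]
        if config.noise_sd > 0:
            data += config.noise_sd * rng.standard_normal(data.shape)
        # motion: slow random walk, translations in mm, rotations in rad
        steps = rng.standard_normal((n_time, 6))
        steps[:, :3] *= 0.02
        steps[:, 3:] *= 0.002
        motion = np.cumsum(steps, axis=0)
        # spikes: global intensity offsets on randomly chosen volumes
        spike_mask = rng.random(n_time) < config.spike_rate
        spike_mask[0] = False
        spikes = set(np.nonzero(spike_mask)[0].tolist())
        for idx in spikes:
            data[..., idx] += SPIKE_FRACTION * config.baseline_intensity
        runs.append(BoldRun(data=data, tr_seconds=config.tr_seconds))
        nuisances.append(NuisanceSet(motion=motion, spikes=spikes))
        latents_out.append(latents)
    truth.latent_signals[subject_id] = latents_out
    return SubjectData(subject_id=subject_id, runs=runs,
                       nuisance=nuisances, latents=latents_out)


def simulate_group(config: PhantomConfig):
    """Anatomy, ground truth, one event table per run, and all subjects.

    Subject seeds are spawned deterministically from ``config.rng_seed``.
    """
    anatomy, truth = build_phantom_anatomy(config)
    events = [make_event_table(config) for _ in range(config.n_runs)]
    children = np.random.SeedSequence(config.rng_seed).spawn(config.n_subjects)
    subjects = []
    for i, child in enumerate(children):
        sid = f"sub-{i + 1:02d}"
        seed = int(child.generate_state(1)[0] % (2**31 - 1))
        subjects.append(synthesize_subject(anatomy, truth, events[0],
                                           config, seed, subject_id=sid))
    return anatomy, truth, events, subjects
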