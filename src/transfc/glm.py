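"""Task GLM: spike detection, design construction, OLS fit, contrasts.

The GLM serves two downstream purposes.  Its residuals — task, motion and
spike effects regressed out — are the input to the intrinsic functional
connectivity analysis, yielding a dataset that behaves like resting state.
Its condition betas yield the scene>baseline and object>baseline contrast
maps for the content-bias analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import gammaln

from .exceptions import InvalidInputError

log = logging.getLogger(__name__)

#: FWHM -> Gaussian sigma conversion constant, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class BoldRun:
    """One subject's 4D time series (x, y, z, time) with its TR."""

    data: np.ndarray
    tr_seconds: float

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


@dataclass
class NuisanceSet:
    """Regressors of no interest for one run.

    ``motion`` is a time x 6 matrix (3 translations in mm, 3 rotations in
    radians); ``spikes`` the detected/injected outlier volume indices;
    white-matter and CSF mean series are attached once extracted.
    """

    motion: np.ndarray
    spikes: Set[int] = field(default_factory=set)
    wm_series: Optional[np.ndarray] = None
    csf_series: Optional[np.ndarray] = None


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # time x n_columns
    names: Sequence[str]

    def column(self, name: str) -> np.ndarray:
        try:
            idx = list(self.names).index(name)
        except ValueError:
            raise InvalidInputError(f"no design column named {name!r}") from None
        return self.matrix[:, idx]


@dataclass
class GlmFit:
    betas: np.ndarray           # n_columns x (x, y, z)
    residual_run: BoldRun
    design: DesignMatrix


@dataclass
class ContrastMap:
    values: np.ndarray          # 3D
    contrast_name: str


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Gamma density, zero for t <= 0; avoids scipy.stats overhead."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((shape - 1) * np.log(tp) - tp / scale
                      - gammaln(shape) - shape * np.log(scale))
    return out


def canonical_hrf(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``tr``.

    Peak gamma with shape 6, undershoot with shape 16 (both scale 1 s),
    undershoot ratio 1/6 — the conventional parameterisation, peaking
    near 5 s.  The kernel is normalised to sum to one so that convolution
    preserves the boxcar amplitude scale.
    """
    if tr <= 0:
        raise InvalidInputError("tr must be positive")
    if duration_s < 16:
        raise InvalidInputError("duration_s must be >= 16 s")
    t = np.arange(0.0, duration_s + 1e-9, tr)
    kernel = _gamma_pdf(t, 6.0, 1.0) - _gamma_pdf(t, 16.0, 1.0) / 6.0
    return kernel / kernel.sum()


def convolve_events(onsets: np.ndarray, durations: np.ndarray, n_time: int,
                    tr: float, oversample: int = 10) -> np.ndarray:
    """HRF-convolved boxcar regressor for one condition, sampled at the TR.

    Built on an oversampled grid (``tr / oversample``) so that onsets need
    not fall on volume boundaries.
    """
    dt = tr / oversample
    n_fine = n_time * oversample
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        box[i0:min(i1, n_fine)] = 1.0
    kernel = canonical_hrf(dt)
    fine = np.convolve(box, kernel)[:n_fine]
    return fine[::oversample][:n_time]


def detect_spikes(run: BoldRun, motion: np.ndarray,
                  intensity_pct: float = 1.3,
                  motion_mm: float = 0.3) -> Set[int]:
    """Flag outlier volumes by global-intensity change or framewise motion.

    A volume is flagged when the scan-to-scan change of its global mean
    intensity exceeds ``intensity_pct`` percent of the run-mean intensity,
    or when the framewise displacement (sum of absolute scan-to-scan
    translation differences, in mm) exceeds ``motion_mm``.  The first
    volume has no predecessor and is never intensity-flagged.
    """
    if run.n_volumes < 2:
        raise InvalidInputError("spike detection needs at least 2 volumes")
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != run.n_volumes:
        raise InvalidInputError(
            f"motion rows ({motion.shape[0]}) != run length ({run.n_volumes})")
    global_mean = run.data.reshape(-1, run.n_volumes).mean(axis=0)
    run_mean = global_mean.mean()
    pct_change = 100.0 * np.abs(np.diff(global_mean)) / run_mean
    flagged = set(np.nonzero(pct_change > intensity_pct)[0] + 1)
    fd = np.abs(np.diff(motion[:, :3], axis=0)).sum(axis=1)
    flagged |= set(np.nonzero(fd > motion_mm)[0] + 1)
    return flagged


def build_design(events: Optional[pd.DataFrame], nuisance: NuisanceSet,
                 n_time: int, tr: float) -> DesignMatrix:
    """Assemble condition, motion, spike and intercept columns.

    Condition columns are HRF-convolved boxcars (one per condition present
    in the event table, in scene/object/baseline order); spike columns are
    one-hot indicators; the intercept absorbs the offset, so condition
    columns are not mean-centred.
    """
    cols, names = [], []
    if events is not None and len(events):
        from .config import CONDITIONS
        present = [c for c in CONDITIONS if c in set(events["condition"])]
        present += sorted(set(events["condition"]) - set(CONDITIONS))
        for cond in present:
            sel = events[events["condition"] == cond]
            reg = convolve_events(sel["onset"].to_numpy(),
                                  sel["duration"].to_numpy(), n_time, tr)
            cols.append(reg)
            names.append(cond)
    motion = np.asarray(nuisance.motion, dtype=float)
    if motion.shape[0] != n_time:
        raise InvalidInputError("motion length does not match run length")
    for j in range(motion.shape[1]):
        cols.append(motion[:, j])
        names.append(f"motion{j + 1}")
    for idx in sorted(nuisance.spikes):
        if not (0 <= idx < n_time):
            raise InvalidInputError(f"spike index {idx} outside run")
        one_hot = np.zeros(n_time)
        one_hot[idx] = 1.0
        cols.append(one_hot)
        names.append(f"spike{idx}")
    cols.append(np.ones(n_time))
    names.append("intercept")
    matrix = np.column_stack(cols)
    rank = np.linalg.matrix_rank(matrix)
    if rank < matrix.shape[1]:
        collinear = _find_collinear(matrix, names)
        raise InvalidInputError(
            f"design matrix rank {rank} < {matrix.shape[1]} columns; "
            f"collinear columns: {collinear}")
    return DesignMatrix(matrix=matrix, names=names)


def _find_collinear(matrix: np.ndarray, names: Sequence[str]) -> list:
    """Name columns whose removal restores full rank (diagnostic only)."""
    bad = []
    full = np.linalg.matrix_rank(matrix)
    for j, name in enumerate(names):
        reduced = np.delete(matrix, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            bad.append(name)
    return bad


def fit_glm(run: BoldRun, design: DesignMatrix) -> GlmFit:
    """Voxelwise ordinary least squares; residuals keep the run's shape."""
    X = design.matrix
    n_time = run.n_volumes
    if X.shape[0] != n_time:
        raise InvalidInputError("design rows do not match run length")
    Y = run.data.reshape(-1, n_time).T          # time x voxels
    if not np.all(np.isfinite(Y)):
        bad = np.argwhere(~np.isfinite(run.data))
        coord = tuple(int(i) for i in bad[0][:3])
        raise InvalidInputError(f"non-finite voxel series, first at voxel {coord}")
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    spatial = run.data.shape[:3]
    betas_vol = betas.reshape(X.shape[1], *spatial)
    resid_run = BoldRun(data=np.moveaxis(resid, 0, -1).reshape(*spatial, n_time),
                        tr_seconds=run.tr_seconds)
    return GlmFit(betas=betas_vol, residual_run=resid_run, design=design)


def contrast(fit: GlmFit, weights: Mapping[str, float],
             name: Optional[str] = None) -> ContrastMap:
    """Per-voxel dot product of betas with named contrast weights."""
    names = list(fit.design.names)
    values = np.zeros(fit.betas.shape[1:])
    for col, w in weights.items():
        if col not in names:
            raise InvalidInputError(f"unknown design column {col!r}")
        values += w * fit.betas[names.index(col)]
    if name is None:
        name = "+".join(f"{w:+g}*{c}" for c, w in weights.items())
    return ContrastMap(values=values, contrast_name=name)


def smooth_volume(volume: np.ndarray, fwhm_mm: float,
                  voxel_size_mm: float = 1.0) -> np.ndarray:
    """Gaussian smoothing with sigma = FWHM / (2*sqrt(2 ln 2)) voxels."""
    if fwhm_mm < 0:
        raise InvalidInputError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    sigma = fwhm_mm / FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma)


def smooth_run(run: BoldRun, fwhm_mm: float, voxel_size_mm: float = 1.0) -> BoldRun:
    """Apply :func:`smooth_volume` to every volume of a run."""
    if fwhm_mm == 0:
        return BoldRun(data=run.data.copy(), tr_seconds=run.tr_seconds)
    sigma = fwhm_mm / FWHM_TO_SIGMA / voxel_size_mm
    smoothed = ndimage.gaussian_filter(run.data, sigma=(sigma, sigma, sigma, 0.0))
    return BoldRun(data=smoothed, tr_seconds=run.tr_seconds)
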