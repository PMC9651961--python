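"""Seed-to-voxel semipartial correlation on GLM residuals.

The semipartial correlation isolates the variance in each voxel that is
*uniquely* explained by the seed: the seed time series is residualized
against the other seeds (controls) plus nuisance regressors, while voxel
series are cleaned of nuisance only.  This asymmetry matters — toolboxes
differ on which side is partialled — and is fixed here on the seed side.
All series are band-pass filtered (default 0.01-0.1 Hz) with a zero-phase
FFT mask before correlation, and correlations are Fisher z-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import InvalidConfigError, InvalidInputError
from .glm import BoldRun

log = logging.getLogger(__name__)

#: correlations are clipped to +-(1 - CLIP_EPS) before atanh
CLIP_EPS = 1e-7


@dataclass
class ConnectivityMap:
    """Per-voxel Fisher-z semipartial correlation for one seed, one subject."""

    z_values: np.ndarray        # 3D, NaN outside the analyzed mask
    seed_name: str
    subject_id: str


def intensity_exclude(mask: np.ndarray, run: BoldRun,
                      k_sd: float = 2.0) -> np.ndarray:
    """Drop low-intensity ROI voxels (signal dropout) from a seed mask.

    Keeps voxels whose temporal-mean intensity is at least
    ``mean - k_sd * SD`` of the ROI voxel means (sample SD over ROI
    voxels).  ``k_sd=inf`` disables the exclusion.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("intensity_exclude: empty mask")
    if np.isinf(k_sd):
        return mask.copy()
    voxel_means = run.data[mask].mean(axis=-1)
    if voxel_means.size < 2:
        return mask.copy()
    threshold = voxel_means.mean() - k_sd * voxel_means.std(ddof=1)
    keep = voxel_means >= threshold
    if not keep.any():
        raise InvalidInputError("intensity_exclude removed every voxel; "
                                "seed unusable")
    out = np.zeros_like(mask)
    out[np.nonzero(mask)] = keep
    return out


def mean_timeseries(run: BoldRun, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the mask's voxels at each timepoint."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("mean_timeseries: empty voxel set")
    return run.data[mask].mean(axis=0)


def bandpass(series: np.ndarray, band: Tuple[float, float],
             tr: float) -> np.ndarray:
    """Zero-phase band-pass by FFT masking; DC is always removed.

    Accepts a vector (time,) or a matrix (time, k); filtering is applied
    along the first axis.  The passband [low, high] is exact at the
    discrete Fourier frequencies, which makes the filter deterministic and
    directly testable against an FFT amplitude-ratio oracle.
    """
    low, high = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < low < high <= nyquist + 1e-12):
        raise InvalidConfigError(f"band {band} invalid for TR {tr}")
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n_time = x.shape[0]
    if n_time * tr < 3.0 / low:
        log.warning("bandpass: series (%.0f s) shorter than 3 cycles of the "
                    "low cutoff (%.4f Hz); filtering anyway", n_time * tr, low)
    spectrum = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n_time, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    keep[0] = False
    spectrum[~keep] = 0.0
    out = np.fft.irfft(spectrum, n=n_time, axis=0)
    return out[:, 0] if squeeze else out


def _residualize(y: np.ndarray, X: Optional[np.ndarray]) -> np.ndarray:
    """OLS residual of y (time or time x k) on X plus an intercept."""
    y = np.asarray(y, dtype=float)
    if X is None or X.size == 0:
        return y - y.mean(axis=0, keepdims=True) if y.ndim > 1 else y - y.mean()
    X = np.column_stack([np.ones(X.shape[0]), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def fisher_z(r):
    """atanh with clipping at 1 - 1e-7; rejects |r| > 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise InvalidInputError("fisher_z: |r| > 1")
    clipped = np.clip(r, -(1.0 - CLIP_EPS), 1.0 - CLIP_EPS)
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


def semipartial_connectivity(residual_run: BoldRun, seed_series: np.ndarray,
                             control_series: Sequence[np.ndarray],
                             nuisance: Optional[np.ndarray],
                             band: Tuple[float, float],
                             mask: Optional[np.ndarray] = None,
                             seed_name: str = "seed",
                             subject_id: str = "sub") -> ConnectivityMap:
    """Fisher-z map of the unique seed-to-voxel correlation.

    Steps: (1) band-pass seed, controls, nuisance and voxel series;
    (2) residualize voxel series against nuisance; (3) residualize the
    seed against controls + nuisance (unique-seed variance); (4) Pearson
    correlation; (5) Fisher z with clipping.
    """
    tr = residual_run.tr_seconds
    n_time = residual_run.n_volumes
    seed = np.asarray(seed_series, dtype=float)
    if seed.shape[0] != n_time:
        raise InvalidInputError("seed series length does not match run")
    controls = [np.asarray(c, dtype=float) for c in control_series]
    if any(c.shape[0] != n_time for c in controls):
        raise InvalidInputError("control series length does not match run")
    if nuisance is not None and len(nuisance) and np.shape(nuisance)[0] != n_time:
        raise InvalidInputError("nuisance rows do not match run length")

    seed_f = bandpass(seed, band, tr)
    controls_f = [bandpass(c, band, tr) for c in controls]
    nuis_f = None
    if nuisance is not None and np.size(nuisance):
        nuis_f = bandpass(np.asarray(nuisance, dtype=float), band, tr)

    if mask is None:
        mask = np.ones(residual_run.data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    voxels = residual_run.data[mask].T          # time x n_voxels
    voxels_f = bandpass(voxels, band, tr)
    voxels_clean = _residualize(voxels_f, nuis_f)

    design_parts = controls_f + ([nuis_f] if nuis_f is not None else [])
    X = np.column_stack(design_parts) if design_parts else None
    seed_res = _residualize(seed_f, X)
    seed_sd = seed_res.std()
    if seed_sd < 1e-12:
        raise InvalidInputError(
            "seed series has zero variance after residualization; it is "
            "fully explained by the control/nuisance regressors")

    sc = seed_res - seed_res.mean()
    vc = voxels_clean - voxels_clean.mean(axis=0, keepdims=True)
    denom = np.sqrt((sc @ sc) * (vc * vc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (vc.T @ sc) / denom, 0.0)
    z = fisher_z(np.clip(r, -1.0, 1.0))
    z_map = np.full(residual_run.data.shape[:3], np.nan)
    z_map[mask] = z
    return ConnectivityMap(z_values=z_map, seed_name=seed_name,
                           subject_id=subject_id)
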