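"""Transversal segmentation of subiculum and CA1, and segment extraction.

Within each coronal slice the subiculum is cut into five equal-width bins
along the medial-lateral coordinate, and CA1 into three 60-degree sectors
around the midpoint of its longest chord.  Segment indices always run
proximal = 1 to distal = max.  Per-segment means of any 3D map are
computed slice by slice and then averaged (unweighted by default) along
the longitudinal axis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateSliceError, InvalidInputError

log = logging.getLogger(__name__)


@dataclass
class TransversalSegmentation:
    """Per-voxel segment index (0 outside the ROI) plus slice bookkeeping."""

    segments: np.ndarray        # 3D int
    n_segments: int
    coronal_axis: int
    roi_name: str


def segment_subiculum_slice(coords: np.ndarray, n_segments: int = 5,
                            flip: bool = False) -> np.ndarray:
    """Equal-width bins of in-plane voxels along the medial-lateral axis.

    ``coords`` is an (m, 2) array of (medial-lateral, inferior-superior)
    voxel coordinates; binning uses the first column only:
    label = 1 + floor(n * (x - min) / (max - min + 1)).  With
    ``flip=True`` the coordinate is reversed first, anchoring label 1 at
    the high end (used when the proximal end is lateral).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    x = coords[:, 0]
    if np.unique(x).size < n_segments:
        raise DegenerateSliceError(
            f"slice has {np.unique(x).size} distinct medial-lateral "
            f"coordinates, fewer than {n_segments} segments")
    if flip:
        x = x.max() - x + x.min()
    lo, hi = x.min(), x.max()
    labels = 1 + np.floor(n_segments * (x - lo) / (hi - lo + 1)).astype(int)
    return labels


def segment_ca1_slice(coords: np.ndarray, angle_deg: float = 60.0,
                      flip: bool = False) -> np.ndarray:
    """Angular sectors of an in-plane CA1 slice.

    The two ''outer borders'' are taken as the voxel pair at maximum
    in-plane distance (lexicographic tie-break).  Each voxel's unsigned
    angle to the chord direction, measured from the chord midpoint, is
    binned into sectors of ``angle_deg`` (half-open, the last closed at
    180 degrees).  Label 1 is anchored at the proximal endpoint: the
    endpoint with the smaller medial-lateral coordinate, or the larger one
    when ``flip=True``.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 3:
        raise DegenerateSliceError("CA1 slice needs at least 3 voxels")
    # maximum-distance pair, deterministic under ties
    best = None
    for i, j in itertools.combinations(range(coords.shape[0]), 2):
        d = float(np.sum((coords[i] - coords[j]) ** 2))
        key = (d, tuple(-coords[min(i, j)]), tuple(-coords[max(i, j)]))
        if best is None or key > best[0]:
            best = (key, i, j)
    _, i, j = best
    p, q = coords[i], coords[j]
    if np.allclose(p, q):
        raise DegenerateSliceError("CA1 slice has zero in-plane extent")
    # proximal endpoint per axis metadata
    pts = sorted([p, q], key=lambda v: (v[0], v[1]))
    prox = pts[-1] if flip else pts[0]
    mid = (p + q) / 2.0
    u = prox - mid
    u = u / np.linalg.norm(u)
    v = coords - mid
    norms = np.linalg.norm(v, axis=1)
    if np.all(norms < 1e-12):
        raise DegenerateSliceError("all CA1 voxels coincide with the midpoint")
    cosang = np.zeros(coords.shape[0])
    nz = norms > 1e-12
    cosang[nz] = (v[nz] @ u) / norms[nz]
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    theta[~nz] = 90.0     # midpoint voxel: middle sector
    n_segments = int(np.ceil(180.0 / angle_deg))
    labels = 1 + np.minimum((theta // angle_deg).astype(int), n_segments - 1)
    return labels


def segment_roi(labels3d: np.ndarray, roi_label: int, axes: Mapping,
                kind: str, n_segments: int = 5, angle_deg: float = 60.0,
                roi_name: str = "") -> TransversalSegmentation:
    """Segment every coronal slice of an ROI in a label map.

    ``kind`` is ``"bins"`` (subiculum rule) or ``"sectors"`` (CA1 rule).
    Slices that cannot be segmented are skipped with a warning.  The
    proximal anchor is taken from ``axes["proximal_lateral"][roi_name]``.
    """
    cor = axes["coronal_axis"]
    medlat = axes["medlat_axis"]
    flip = bool(axes.get("proximal_lateral", {}).get(roi_name, False))
    mask = labels3d == roi_label
    if not mask.any():
        raise InvalidInputError(f"ROI label {roi_label} has no voxels")
    seg = np.zeros_like(labels3d, dtype=np.int16)
    inplane_axes = [a for a in range(3) if a != cor]
    # order in-plane coordinates as (medial-lateral, inferior-superior)
    inplane_axes.sort(key=lambda a: a != medlat)
    n_out = n_segments if kind == "bins" else int(np.ceil(180.0 / angle_deg))
    for y in range(labels3d.shape[cor]):
        slicer = [slice(None)] * 3
        slicer[cor] = y
        sl_mask = mask[tuple(slicer)]
        if not sl_mask.any():
            continue
        vox = np.argwhere(mask & (np.indices(labels3d.shape)[cor] == y))
        coords = vox[:, inplane_axes].astype(float)
        try:
            if kind == "bins":
                lab = segment_subiculum_slice(coords, n_segments, flip=flip)
            elif kind == "sectors":
                lab = segment_ca1_slice(coords, angle_deg, flip=flip)
            else:
                raise InvalidInputError(f"unknown segmentation kind {kind!r}")
        except DegenerateSliceError as exc:
            log.warning("skipping coronal slice %d of %s: %s", y, roi_name, exc)
            continue
        seg[tuple(vox.T)] = lab
    if not (seg > 0).any():
        raise InvalidInputError(f"no slice of {roi_name} could be segmented")
    return TransversalSegmentation(segments=seg, n_segments=n_out,
                                   coronal_axis=cor, roi_name=roi_name)


def extract_segment_profile(volume: np.ndarray,
                            segmentation: TransversalSegmentation,
                            voxel_weighted: bool = False) -> np.ndarray:
    """Per-segment means, computed per coronal slice then averaged.

    By default every slice contributes equally to the longitudinal average
    regardless of its voxel count; ``voxel_weighted=True`` pools voxels
    across slices instead.
    """
    seg = segmentation.segments
    if volume.shape != seg.shape:
        raise InvalidInputError("map and segmentation grids differ")
    cor = segmentation.coronal_axis
    n_seg = segmentation.n_segments
    sums = np.zeros(n_seg)
    weights = np.zeros(n_seg)
    for y in range(seg.shape[cor]):
        slicer = [slice(None)] * 3
        slicer[cor] = y
        seg_sl = seg[tuple(slicer)]
        vol_sl = volume[tuple(slicer)]
        for s in range(1, n_seg + 1):
            m = seg_sl == s
            if not m.any():
                continue
            if voxel_weighted:
                sums[s - 1] += vol_sl[m].sum()
                weights[s - 1] += m.sum()
            else:
                sums[s - 1] += vol_sl[m].mean()
                weights[s - 1] += 1
    if np.any(weights == 0):
        empty = [s + 1 for s in range(n_seg) if weights[s] == 0]
        raise InvalidInputError(f"segments {empty} empty on every slice")
    return sums / weights


def build_estimate_table(subject_maps: Mapping[str, Mapping[str, np.ndarray]],
                         segmentation: TransversalSegmentation,
                         measures: Sequence[str] = None,
                         voxel_weighted: bool = False) -> pd.DataFrame:
    """Long-format table: subject, measure, segment, value.

    ``subject_maps`` maps subject id -> {measure name -> 3D map}; every
    subject must provide every measure.  This is the sole input format of
    the stats module (the same schema a TSV of deposited segment-level
    estimates would be read into).
    """
    subjects = list(subject_maps)
    if measures is None:
        measures = list(subject_maps[subjects[0]])
    rows = []
    for sid in subjects:
        for measure in measures:
            if measure not in subject_maps[sid]:
                raise InvalidInputError(
                    f"subject {sid!r} is missing measure {measure!r}")
            profile = extract_segment_profile(subject_maps[sid][measure],
                                              segmentation, voxel_weighted)
            for s, val in enumerate(profile, start=1):
                rows.append((sid, measure, s, val))
    return pd.DataFrame(rows, columns=["subject", "measure", "segment", "value"])


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path, column_map: Dict[str, str] = None) -> pd.DataFrame:
    """Read a segment-estimate TSV, optionally renaming foreign columns."""
    table = pd.read_csv(path, sep="\t")
    if column_map:
        table = table.rename(columns=column_map)
    required = {"subject", "measure", "segment", "value"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(f"table lacks columns {sorted(missing)}")
    return table
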