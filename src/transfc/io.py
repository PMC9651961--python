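"""NIfTI / TSV / JSON readers and writers shared by pipeline and CLI."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import BoldRun


def save_nifti(data: np.ndarray, path, voxel_size_mm: float = 1.0,
               tr_seconds: Optional[float] = None) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    if tr_seconds is not None and data.ndim == 4:
        img.header.set_zooms((voxel_size_mm,) * 3 + (tr_seconds,))
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_bold_run(run: BoldRun, path, voxel_size_mm: float = 1.0) -> None:
    save_nifti(run.data.astype(np.float32), path, voxel_size_mm,
               tr_seconds=run.tr_seconds)


def load_bold_run(path, tr_seconds: Optional[float] = None) -> BoldRun:
    img = nib.load(str(path))
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3])
    return BoldRun(data=np.asarray(img.get_fdata()), tr_seconds=tr_seconds)


def save_label_map(labels: np.ndarray, legend: Dict[int, str], axes: dict,
                   path, voxel_size_mm: float = 1.0) -> None:
    """Integer label NIfTI plus a JSON sidecar with legend and axis metadata."""
    save_nifti(labels.astype(np.int16), path, voxel_size_mm)
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"legend": {str(k): v for k, v in legend.items()},
                   "axes": axes}, fh, indent=1)


def save_events_tsv(events: pd.DataFrame, path) -> None:
    out = events.rename(columns={"condition": "trial_type"})
    out.to_csv(path, sep="\t", index=False)


def load_events_tsv(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    return events.rename(columns={"trial_type": "condition"})


def save_motion_tsv(motion: np.ndarray, path) -> None:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    pd.DataFrame(motion, columns=cols).to_csv(path, sep="\t", index=False)


def load_motion_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
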