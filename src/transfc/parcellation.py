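"""Group-level winner-take-all definition of entorhinal seed regions.

Per-subject Fisher-z connectivity maps (one per cortical source) are
combined into one-sample T maps; each entorhinal voxel is then attributed
to the source with the maximum supra-threshold T (default T > 3.1), and
seed sizes are equalized across hemispheres by keeping, per source, the N
highest-preference voxels where N is the smaller hemisphere's count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .config import SOURCE_ORDER
from .exceptions import InvalidInputError

log = logging.getLogger(__name__)


@dataclass
class TMap:
    t_values: np.ndarray        # 3D
    df: int
    source_name: str


@dataclass
class SeedAssignment:
    """Per-voxel winning source (0 = unassigned) with its winning T value."""

    labels: np.ndarray          # 3D int, index into source_order, 1-based
    winning_t: np.ndarray       # 3D float, NaN where unassigned
    source_order: Sequence[str] = field(default=SOURCE_ORDER)

    def mask(self, source: str) -> np.ndarray:
        return self.labels == (list(self.source_order).index(source) + 1)

    def counts(self) -> Dict[str, int]:
        return {s: int(self.mask(s).sum()) for s in self.source_order}


def one_sample_tmap(z_maps: Sequence[np.ndarray],
                    source_name: str = "") -> TMap:
    """Voxelwise one-sample t statistic across subjects (df = n - 1).

    Voxels with zero sample SD get a signed-infinity sentinel (0 when the
    mean is also zero) and are logged.
    """
    stack = np.asarray(z_maps, dtype=float)
    n = stack.shape[0]
    if n < 2:
        raise InvalidInputError("one_sample_tmap needs >= 2 subjects")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    if degenerate.any():
        nonnull = degenerate & (mean != 0)
        if nonnull.any():
            log.warning("one_sample_tmap[%s]: %d voxels with zero SD and "
                        "nonzero mean -> signed-infinity sentinel",
                        source_name, int(nonnull.sum()))
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate, np.sign(mean) * np.inf, t)
        t = np.where(degenerate & (mean == 0), 0.0, t)
    return TMap(t_values=t, df=n - 1, source_name=source_name)


def winner_take_all(tmaps: Mapping[str, TMap], t_threshold: float = 3.1,
                    mask: np.ndarray = None,
                    source_order: Sequence[str] = SOURCE_ORDER) -> SeedAssignment:
    """Assign each voxel to the argmax-T source where that T > threshold.

    Ties are broken by the fixed source order (argmax keeps the first
    maximum) and logged; sub-threshold voxels stay unassigned.
    """
    missing = [s for s in source_order if s not in tmaps]
    if missing:
        raise InvalidInputError(f"missing T maps for sources: {missing}")
    stack = np.stack([tmaps[s].t_values for s in source_order])
    if mask is None:
        mask = np.ones(stack.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    winner = np.argmax(stack, axis=0)
    win_t = np.take_along_axis(stack, winner[None], axis=0)[0]
    ties = ((stack == win_t[None]).sum(axis=0) > 1) & mask & (win_t > t_threshold)
    if ties.any():
        log.warning("winner_take_all: %d tied voxels broken by source order "
                    "%s", int(ties.sum()), tuple(source_order))
    assigned = mask & (win_t > t_threshold)
    labels = np.where(assigned, winner + 1, 0).astype(np.int16)
    winning_t = np.where(assigned, win_t, np.nan)
    return SeedAssignment(labels=labels, winning_t=winning_t,
                          source_order=tuple(source_order))


def equalize_across_hemispheres(
        assignments: Mapping[str, SeedAssignment]) -> Dict[str, SeedAssignment]:
    """Equalize per-source voxel counts across hemispheres.

    For each source, N = the minimum assigned-voxel count over hemispheres;
    each hemisphere keeps its N voxels with the highest winning T for that
    source (deterministic: ties broken by flat voxel index).  With a single
    hemisphere this is the identity.  A source empty in any hemisphere is
    emptied everywhere, with a warning.
    """
    hemis = list(assignments)
    if not hemis:
        raise InvalidInputError("no hemispheres given")
    order = assignments[hemis[0]].source_order
    out: Dict[str, SeedAssignment] = {
        h: SeedAssignment(labels=a.labels.copy(),
                          winning_t=a.winning_t.copy(),
                          source_order=a.source_order)
        for h, a in assignments.items()}
    for k, source in enumerate(order, start=1):
        counts = {h: int((assignments[h].labels == k).sum()) for h in hemis}
        n_keep = min(counts.values())
        if n_keep == 0 and max(counts.values()) > 0:
            log.warning("equalize: source %s empty in one hemisphere; "
                        "its seed is emptied in all hemispheres", source)
        for h in hemis:
            a = out[h]
            flat_idx = np.nonzero(a.labels.ravel() == k)[0]
            if flat_idx.size <= n_keep:
                continue
            t_vals = a.winning_t.ravel()[flat_idx]
            drop_order = np.lexsort((flat_idx, -t_vals))
            drop = flat_idx[drop_order][n_keep:]
            lab_flat = a.labels.ravel()
            t_flat = a.winning_t.ravel()
            lab_flat[drop] = 0
            t_flat[drop] = np.nan
    return out


def parcellation_accuracy(assignment: SeedAssignment,
                          true_sublabel: np.ndarray,
                          ec_mask: np.ndarray) -> float:
    """Fraction of EC voxels attributed to their generating source."""
    ec_mask = np.asarray(ec_mask, dtype=bool)
    total = int(ec_mask.sum())
    if total == 0:
        raise InvalidInputError("empty EC mask")
    correct = int(((assignment.labels == true_sublabel) & ec_mask).sum())
    return correct / total
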