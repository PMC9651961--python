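"""Repeated-measures ANOVA cascade, BH-FDR, and post-hoc paired t-tests.

The inference layer is organised statsmodels-style: a model object is
built from a long-format segment-estimate table and ``fit()`` returns a
results object carrying the statistics, decision log and a ``summary()``
table.  The univariate within-subject ANOVA uses the classical sums-of-
squares decomposition with subject x factor error strata and no sphericity
correction by default, which reproduces the conventional
(a-1)(b-1) / (a-1)(b-1)(n-1) degrees of freedom; Greenhouse-Geisser
correction is available as an option.

Two testing cascades are provided.  The *gradient* hierarchy asks whether
entorhinal seeds differ in their connectivity profile along the
transversal axis of a target region: stage 1 tests the seed x segment
interaction per target region (FDR across regions); stage 2, run only in
significant regions, tests each seed's one-way segment effect (FDR within
region); stage 3, run only when at least two seeds survive, tests the
pairwise seed x segment interactions (uncorrected, logged).  The *content*
cascade tests the condition x region (or segment) interaction and, if
significant, scene-vs-object paired t-tests per region with BH-FDR.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidInputError, ZeroVarianceError

log = logging.getLogger(__name__)


@dataclass
class RmAnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float

    def __str__(self) -> str:
        return (f"{self.effect}: F({self.df_num},{self.df_den}) = "
                f"{self.F:.3f}, p = {self.p:.4g}")


# ---------------------------------------------------------------------------
# core within-subject ANOVA


def _cell_cube(table: pd.DataFrame, dv: str, within: Sequence[str],
               subject: str) -> Tuple[np.ndarray, List[List]]:
    """Complete balanced subject x factor(s) value cube from a long table."""
    cols = [subject] + list(within)
    counts = table.groupby(cols, sort=True)[dv].count()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise InvalidInputError(
            f"table is not complete/balanced (one observation per cell "
            f"required); offending cells: {list(bad.index[:5])}")
    subjects = sorted(table[subject].unique())
    levels = [sorted(table[f].unique()) for f in within]
    expected = len(subjects) * int(np.prod([len(l) for l in levels]))
    if len(table) != expected:
        raise InvalidInputError("missing cells in the estimate table")
    pivoted = table.set_index(cols)[dv].sort_index()
    cube = pivoted.to_numpy().reshape([len(subjects)] + [len(l) for l in levels])
    return cube, levels


def _f_and_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int,
             gg_epsilon: float = 1.0,
             tol: float = 0.0) -> Tuple[float, float, int, int]:
    # ``tol`` is a relative floor (fraction of total SS) below which a sum
    # of squares counts as exactly zero, so duplicated factor levels give
    # F = 0 instead of a ratio of rounding residues
    if ss_eff <= tol:
        return 0.0, 1.0, df_eff, df_err
    if ss_err <= tol:
        return np.inf, 0.0, df_eff, df_err
    F = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_eff * gg_epsilon, df_err * gg_epsilon))
    return float(F), p, df_eff, df_err


def _gg_epsilon(diffs: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance of within-cell scores."""
    S = np.cov(diffs.reshape(diffs.shape[0], -1), rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    num = (k * (mean_diag - S.mean())) ** 2
    den = (k - 1) * ((S ** 2).sum() - 2 * k * (S.mean(axis=0) ** 2).sum()
                     + k ** 2 * S.mean() ** 2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0)) if den > 0 else 1.0


def rm_anova(table: pd.DataFrame, dv: str = "value",
             within: Sequence[str] = ("measure", "segment"),
             subject: str = "subject",
             gg_correction: bool = False) -> List[RmAnovaResult]:
    """Classical univariate repeated-measures ANOVA on a long table.

    One or two within-subject factors; returns main effects (and the
    interaction for two factors).  Error strata are the subject x effect
    interactions, giving df_den = df_effect * (n - 1).
    """
    within = [w for w in within if w is not None]
    if not 1 <= len(within) <= 2:
        raise InvalidInputError("rm_anova supports 1 or 2 within factors")
    cube, levels = _cell_cube(table, dv, within, subject)
    n = cube.shape[0]
    if n < 2:
        raise InvalidInputError("rm_anova needs >= 2 subjects")
    grand = cube.mean()
    ss_tol = 1e-12 * float(((cube - grand) ** 2).sum())
    results: List[RmAnovaResult] = []

    if len(within) == 1:
        a = cube.shape[1]
        subj_mean = cube.mean(axis=1, keepdims=True)
        a_mean = cube.mean(axis=0, keepdims=True)
        ss_a = n * float(((a_mean - grand) ** 2).sum())
        resid = cube - subj_mean - a_mean + grand
        ss_err = float((resid ** 2).sum())
        eps = _gg_epsilon(cube - subj_mean) if gg_correction else 1.0
        F, p, dfn, dfd = _f_and_p(ss_a, a - 1, ss_err, (a - 1) * (n - 1), eps,
                                  tol=ss_tol)
        results.append(RmAnovaResult(within[0], F, dfn, dfd, p))
        return results

    a, b = cube.shape[1], cube.shape[2]
    m_s = cube.mean(axis=(1, 2))                 # subject means
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_a = n * b * float(((m_a - grand) ** 2).sum())
    ss_b = n * a * float(((m_b - grand) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_sa = b * float(((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_sb = a * float(((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum())
    resid = (cube - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_sab = float((resid ** 2).sum())

    specs = [
        (within[0], ss_a, a - 1, ss_sa, (a - 1) * (n - 1),
         cube.mean(axis=2) - m_s[:, None]),
        (within[1], ss_b, b - 1, ss_sb, (b - 1) * (n - 1),
         cube.mean(axis=1) - m_s[:, None]),
        (f"{within[0]}:{within[1]}", ss_ab, (a - 1) * (b - 1), ss_sab,
         (a - 1) * (b - 1) * (n - 1), cube - m_s[:, None, None]),
    ]
    for name, ss_eff, df_eff, ss_err, df_err, scores in specs:
        eps = _gg_epsilon(scores) if gg_correction else 1.0
        F, p, dfn, dfd = _f_and_p(ss_eff, df_eff, ss_err, df_err, eps,
                                  tol=ss_tol)
        results.append(RmAnovaResult(name, F, dfn, dfd, p))
    return results


# ---------------------------------------------------------------------------
# multiple testing and post-hocs


def fdr_bh(p_values: Sequence[float],
           q: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values).

    Rejects the k smallest p-values where k = max{i : p(i) <= i*q/m};
    adjusted p-values via the backward cumulative-minimum pass.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = np.arange(1, m + 1) * q / m
    below = np.nonzero(ranked <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    return reject, adjusted


def paired_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, int, float]:
    """Paired-samples t-test: (t, df, two-sided p) on the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidInputError("paired_t needs two equal-length vectors, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("paired_t: differences have zero variance")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


# ---------------------------------------------------------------------------
# Model / Results layer


@dataclass
class RmAnovaResults:
    """Fitted repeated-measures ANOVA: effect table plus metadata."""

    effects: List[RmAnovaResult]
    n_subjects: int
    within: Sequence[str]

    def effect(self, name: str) -> RmAnovaResult:
        for eff in self.effects:
            if eff.effect == name:
                return eff
        raise KeyError(name)

    @property
    def interaction(self) -> Optional[RmAnovaResult]:
        for eff in self.effects:
            if ":" in eff.effect:
                return eff
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects])

    def summary(self) -> str:
        lines = [f"Repeated-measures ANOVA (n={self.n_subjects}, within="
                 f"{'x'.join(self.within)})"]
        lines += [f"  {e}" for e in self.effects]
        return "\n".join(lines)


class RmAnova:
    """Repeated-measures ANOVA model on a long-format table.

    Parameters
    ----------
    table : long DataFrame with one observation per subject x cell
    dv, within, subject : column names (1 or 2 within factors)
    """

    def __init__(self, table: pd.DataFrame, dv: str = "value",
                 within: Sequence[str] = ("measure", "segment"),
                 subject: str = "subject", gg_correction: bool = False):
        self.table = table
        self.dv = dv
        self.within = [w for w in within if w is not None]
        self.subject = subject
        self.gg_correction = gg_correction

    def fit(self) -> RmAnovaResults:
        effects = rm_anova(self.table, self.dv, self.within, self.subject,
                           self.gg_correction)
        n = self.table[self.subject].nunique()
        return RmAnovaResults(effects=effects, n_subjects=n,
                              within=self.within)


@dataclass
class RegionGradientResult:
    region: str
    interaction: RmAnovaResult
    interaction_p_fdr: float
    significant: bool
    seed_main_effects: Dict[str, RmAnovaResult] = field(default_factory=dict)
    seed_p_fdr: Dict[str, float] = field(default_factory=dict)
    significant_seeds: List[str] = field(default_factory=list)
    pairwise_interactions: Dict[Tuple[str, str], RmAnovaResult] = field(
        default_factory=dict)
    seed_slope_signs: Dict[str, int] = field(default_factory=dict)


@dataclass
class GradientResults:
    """Hierarchy outcome per target region plus the decision log."""

    regions: Dict[str, RegionGradientResult]
    q: float
    decisions: List[str]

    def summary(self) -> str:
        lines = [f"Hierarchical gradient test (BH-FDR q={self.q})"]
        for name, res in self.regions.items():
            flag = "significant" if res.significant else "n.s."
            lines.append(f"[{name}] stage 1 {res.interaction} "
                         f"(p_FDR={res.interaction_p_fdr:.4g}, {flag})")
            for seed, eff in res.seed_main_effects.items():
                mark = "*" if seed in res.significant_seeds else " "
                lines.append(f"  stage 2{mark} {seed}: {eff} "
                             f"(p_FDR={res.seed_p_fdr[seed]:.4g})")
            for pair, eff in res.pairwise_interactions.items():
                lines.append(f"  stage 3 {pair[0]} vs {pair[1]}: {eff}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def eff(e):
            return {"effect": e.effect, "F": e.F, "df_num": e.df_num,
                    "df_den": e.df_den, "p": e.p}
        return {
            "q": self.q,
            "decisions": self.decisions,
            "regions": {
                name: {
                    "interaction": eff(r.interaction),
                    "interaction_p_fdr": r.interaction_p_fdr,
                    "significant": bool(r.significant),
                    "seed_main_effects": {s: eff(e) for s, e in
                                          r.seed_main_effects.items()},
                    "seed_p_fdr": {s: float(p) for s, p in r.seed_p_fdr.items()},
                    "significant_seeds": list(r.significant_seeds),
                    "pairwise_interactions": {
                        f"{a}|{b}": eff(e)
                        for (a, b), e in r.pairwise_interactions.items()},
                    "seed_slope_signs": {s: int(v) for s, v in
                                         r.seed_slope_signs.items()},
                }
                for name, r in self.regions.items()},
        }

    def plot_profiles(self, tables: Mapping[str, pd.DataFrame], ax=None):
        """Group-mean segment profile per seed and region (one axes each)."""
        import matplotlib.pyplot as plt
        regions = list(tables)
        fig, axes = plt.subplots(1, len(regions), squeeze=False,
                                 figsize=(4 * len(regions), 3))
        for axis, region in zip(axes[0], regions):
            table = tables[region]
            for seed, grp in table.groupby("measure"):
                prof = grp.groupby("segment")["value"].mean()
                sem = grp.groupby("segment")["value"].sem()
                axis.errorbar(prof.index, prof.to_numpy(), yerr=sem.to_numpy(),
                              label=seed)
            axis.set_title(region)
            axis.set_xlabel("transversal segment (proximal -> distal)")
            axis.set_ylabel("Fisher-z connectivity")
            axis.legend(fontsize="x-small")
        fig.tight_layout()
        return fig


class GradientAnalysis:
    """Hierarchical RM-ANOVA cascade over per-region segment tables.

    ``tables`` maps target-region name (e.g. SUB, CA1) to a long table with
    columns subject/measure(=seed)/segment/value.
    """

    def __init__(self, tables: Mapping[str, pd.DataFrame], q: float = 0.05):
        self.tables = dict(tables)
        self.q = q
        for name, table in self.tables.items():
            if table["measure"].nunique() < 2:
                raise InvalidInputError(
                    f"region {name!r}: gradient hierarchy needs >= 2 seeds")

    def fit(self) -> GradientResults:
        decisions: List[str] = []
        regions: Dict[str, RegionGradientResult] = {}
        names = list(self.tables)
        stage1 = {}
        for name in names:
            res = RmAnova(self.tables[name],
                          within=("measure", "segment")).fit()
            stage1[name] = res.interaction
        reject, adj = fdr_bh([stage1[n].p for n in names], self.q)
        for i, name in enumerate(names):
            decisions.append(
                f"stage1[{name}]: seed x segment interaction p={stage1[name].p:.4g} "
                f"p_FDR={adj[i]:.4g} -> "
                f"{'significant' if reject[i] else 'not significant'} "
                f"(family size {len(names)})")
            regions[name] = RegionGradientResult(
                region=name, interaction=stage1[name],
                interaction_p_fdr=float(adj[i]), significant=bool(reject[i]))

        for name in names:
            table = self.tables[name]
            reg = regions[name]
            # group-mean profile slope sign per seed (descriptive diagnostic)
            for seed, grp in table.groupby("measure"):
                prof = grp.groupby("segment")["value"].mean()
                slope = np.polyfit(prof.index.to_numpy(dtype=float),
                                   prof.to_numpy(), 1)[0]
                reg.seed_slope_signs[str(seed)] = int(np.sign(slope))
            if not reg.significant:
                decisions.append(f"stage2[{name}]: skipped (stage 1 n.s.)")
                continue
            seeds = sorted(table["measure"].unique())
            for seed in seeds:
                sub = table[table["measure"] == seed]
                res = RmAnova(sub, within=("segment",)).fit()
                reg.seed_main_effects[str(seed)] = res.effects[0]
            reject2, adj2 = fdr_bh(
                [reg.seed_main_effects[s].p for s in map(str, seeds)], self.q)
            for j, seed in enumerate(map(str, seeds)):
                reg.seed_p_fdr[seed] = float(adj2[j])
                if reject2[j]:
                    reg.significant_seeds.append(seed)
                decisions.append(
                    f"stage2[{name}][{seed}]: one-way segment effect "
                    f"p={reg.seed_main_effects[seed].p:.4g} p_FDR={adj2[j]:.4g} "
                    f"(family size {len(seeds)})")
            if len(reg.significant_seeds) < 2:
                decisions.append(f"stage3[{name}]: skipped "
                                 f"(<2 significant seeds)")
                continue
            for s1, s2 in itertools.combinations(reg.significant_seeds, 2):
                pair_table = table[table["measure"].isin([s1, s2])]
                res = RmAnova(pair_table, within=("measure", "segment")).fit()
                reg.pairwise_interactions[(s1, s2)] = res.interaction
                decisions.append(
                    f"stage3[{name}][{s1} vs {s2}]: pairwise interaction "
                    f"p={res.interaction.p:.4g} (uncorrected)")
        return GradientResults(regions=regions, q=self.q, decisions=decisions)


@dataclass
class ContentPostHoc:
    unit: str                   # region or segment label
    t: float
    df: int
    p: float
    p_fdr: float
    significant: bool
    scene_gt_object: bool


@dataclass
class ContentResults:
    interaction: RmAnovaResult
    interaction_significant: bool
    post_hoc: List[ContentPostHoc]
    q: float
    decisions: List[str]

    @property
    def scene_biased_units(self) -> List[str]:
        return [ph.unit for ph in self.post_hoc
                if ph.significant and ph.scene_gt_object]

    def summary(self) -> str:
        lines = [f"Content-bias test (q={self.q}): {self.interaction}"]
        for ph in self.post_hoc:
            mark = "*" if ph.significant else " "
            direction = "scene>object" if ph.scene_gt_object else "object>=scene"
            lines.append(f" {mark} {ph.unit}: t({ph.df})={ph.t:.3f} "
                         f"p_FDR={ph.p_fdr:.4g} ({direction})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        i = self.interaction
        return {
            "q": self.q,
            "interaction": {"effect": i.effect, "F": i.F, "df_num": i.df_num,
                            "df_den": i.df_den, "p": i.p},
            "interaction_significant": bool(self.interaction_significant),
            "post_hoc": [{"unit": ph.unit, "t": ph.t, "df": ph.df,
                          "p": ph.p, "p_fdr": ph.p_fdr,
                          "significant": bool(ph.significant),
                          "scene_gt_object": bool(ph.scene_gt_object)}
                         for ph in self.post_hoc],
            "scene_biased_units": self.scene_biased_units,
            "decisions": self.decisions,
        }


class ContentBiasAnalysis:
    """Condition x region/segment interaction with FDR post-hoc t-tests.

    ``table`` is long format with columns subject, condition (exactly
    scene and object), unit column (``unit_col``: region or segment) and
    value.
    """

    def __init__(self, table: pd.DataFrame, unit_col: str = "segment",
                 q: float = 0.05):
        conditions = set(table["condition"].unique())
        if conditions != {"scene", "object"}:
            raise InvalidInputError(
                f"content test needs exactly scene and object conditions, "
                f"got {sorted(conditions)}")
        self.table = table
        self.unit_col = unit_col
        self.q = q

    def fit(self) -> ContentResults:
        decisions: List[str] = []
        res = RmAnova(self.table, within=("condition", self.unit_col)).fit()
        interaction = res.interaction
        significant = interaction.p < self.q
        decisions.append(f"interaction condition x {self.unit_col}: "
                         f"p={interaction.p:.4g} -> "
                         f"{'post-hoc t-tests' if significant else 'stop'}")
        post_hoc: List[ContentPostHoc] = []
        if significant:
            units = sorted(self.table[self.unit_col].unique())
            raw = []
            for unit in units:
                sub = self.table[self.table[self.unit_col] == unit]
                wide = sub.pivot(index="subject", columns="condition",
                                 values="value")
                t, df, p = paired_t(wide["scene"].to_numpy(),
                                    wide["object"].to_numpy())
                raw.append((unit, t, df, p))
            reject, adj = fdr_bh([r[3] for r in raw], self.q)
            for (unit, t, df, p), rej, pf in zip(raw, reject, adj):
                post_hoc.append(ContentPostHoc(
                    unit=str(unit), t=t, df=df, p=p, p_fdr=float(pf),
                    significant=bool(rej), scene_gt_object=t > 0))
                decisions.append(f"post-hoc[{unit}]: t={t:.3f} p={p:.4g} "
                                 f"p_FDR={pf:.4g} (family size {len(raw)})")
        return ContentResults(interaction=interaction,
                              interaction_significant=bool(significant),
                              post_hoc=post_hoc, q=self.q, decisions=decisions)


def hierarchical_gradient_test(tables: Mapping[str, pd.DataFrame],
                               q: float = 0.05) -> GradientResults:
    """Functional wrapper around :class:`GradientAnalysis`."""
    return GradientAnalysis(tables, q=q).fit()


def content_bias_test(table: pd.DataFrame, unit_col: str = "segment",
                      q: float = 0.05) -> ContentResults:
    """Functional wrapper around :class:`ContentBiasAnalysis`."""
    return ContentBiasAnalysis(table, unit_col=unit_col, q=q).fit()
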