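"""RM-ANOVA, BH-FDR, paired t, and the hierarchical testing cascades.

The within-subject ANOVA is cross-checked two ways: an explicit loop-based
sums-of-squares oracle written here, and pingouin's independent
implementation on random balanced fixtures.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import transfc as tf


def _long_table(cube, factors=("measure", "segment")):
    """subjects x a x b value cube -> long DataFrame."""
    n, a, b = cube.shape
    rows = []
    for i, j, k in itertools.product(range(n), range(a), range(b)):
        rows.append((f"s{i:02d}", f"A{j}", k + 1, cube[i, j, k]))
    return pd.DataFrame(rows, columns=["subject", factors[0], factors[1],
                                       "value"])


def _oracle_two_way(cube):
    """Loop-based within-subject SS decomposition (independent formulas)."""
    n, a, b = cube.shape
    grand = cube.mean()
    ss = {"A": 0.0, "B": 0.0, "AB": 0.0, "sA": 0.0, "sB": 0.0, "sAB": 0.0}
    for j in range(a):
        ss["A"] += n * b * (cube[:, j, :].mean() - grand) ** 2
    for k in range(b):
        ss["B"] += n * a * (cube[:, :, k].mean() - grand) ** 2
    for j in range(a):
        for k in range(b):
            ss["AB"] += n * (cube[:, j, k].mean() - cube[:, j, :].mean()
                             - cube[:, :, k].mean() + grand) ** 2
    for i in range(n):
        for j in range(a):
            ss["sA"] += b * (cube[i, j, :].mean() - cube[i].mean()
                             - cube[:, j, :].mean() + grand) ** 2
        for k in range(b):
            ss["sB"] += a * (cube[i, :, k].mean() - cube[i].mean()
                             - cube[:, :, k].mean() + grand) ** 2
        for j in range(a):
            for k in range(b):
                ss["sAB"] += (cube[i, j, k]
                              - cube[i, j, :].mean() - cube[i, :, k].mean()
                              - cube[:, j, k].mean()
                              + cube[i].mean() + cube[:, j, :].mean()
                              + cube[:, :, k].mean() - grand) ** 2
    F = {
        "A": (ss["A"] / (a - 1)) / (ss["sA"] / ((a - 1) * (n - 1))),
        "B": (ss["B"] / (b - 1)) / (ss["sB"] / ((b - 1) * (n - 1))),
        "AB": (ss["AB"] / ((a - 1) * (b - 1)))
              / (ss["sAB"] / ((a - 1) * (b - 1) * (n - 1))),
    }
    return F


class TestRmAnova:
    def test_no_effect_variance_gives_zero_f(self):
        # every subject flat across all cells -> all F = 0
        cube = np.tile(np.arange(3.0)[:, None, None], (1, 2, 4))
        results = tf.rm_anova(_long_table(cube))
        assert all(r.F == 0.0 and r.p == 1.0 for r in results)

    def test_two_by_two_matches_hand_oracle(self, rng):
        cube = rng.normal(size=(3, 2, 2))
        results = {r.effect: r for r in tf.rm_anova(_long_table(cube))}
        oracle = _oracle_two_way(cube)
        assert results["measure"].F == pytest.approx(oracle["A"], abs=1e-10)
        assert results["segment"].F == pytest.approx(oracle["B"], abs=1e-10)
        assert results["measure:segment"].F == pytest.approx(oracle["AB"],
                                                             abs=1e-10)

    @pytest.mark.parametrize("shape", [(4, 2, 3), (6, 3, 4), (8, 4, 5)])
    def test_random_fixtures_match_loop_oracle(self, shape, rng):
        cube = rng.normal(size=shape) + rng.normal(size=(shape[0], 1, 1))
        results = {r.effect: r for r in tf.rm_anova(_long_table(cube))}
        oracle = _oracle_two_way(cube)
        for key, eff in (("A", "measure"), ("B", "segment"),
                         ("AB", "measure:segment")):
            assert results[eff].F == pytest.approx(oracle[key], abs=1e-8)

    @pytest.mark.parametrize("shape", [(5, 2, 2), (8, 4, 5), (6, 3, 2)])
    def test_agrees_with_pingouin(self, shape, rng):
        pg = pytest.importorskip("pingouin")
        cube = rng.normal(size=shape)
        table = _long_table(cube)
        ours = {r.effect: r for r in tf.rm_anova(table)}
        theirs = pg.rm_anova(data=table, dv="value",
                             within=["measure", "segment"],
                             subject="subject", detailed=True)
        for src, eff in (("measure", "measure"), ("segment", "segment"),
                         ("measure * segment", "measure:segment")):
            row = theirs[theirs["Source"] == src].iloc[0]
            assert ours[eff].F == pytest.approx(row["F"], rel=1e-6)
            assert ours[eff].p == pytest.approx(row["p_unc"], rel=1e-5)
            assert ours[eff].df_num == row["ddof1"]
            assert ours[eff].df_den == row["ddof2"]

    def test_one_way_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        cube = rng.normal(size=(7, 4, 1))
        table = _long_table(cube)
        ours = tf.rm_anova(table, within=("measure",))[0]
        theirs = pg.rm_anova(data=table, dv="value", within="measure",
                             subject="subject", detailed=True)
        eff = theirs[theirs["Source"] == "measure"].iloc[0]
        err = theirs[theirs["Source"] == "Error"].iloc[0]
        assert ours.F == pytest.approx(eff["F"], rel=1e-6)
        assert ours.df_num == eff["DF"] and ours.df_den == err["DF"]

    def test_missing_cell_rejected(self, rng):
        table = _long_table(rng.normal(size=(3, 2, 2))).iloc[:-1]
        with pytest.raises(tf.InvalidInputError, match="balanced|missing"):
            tf.rm_anova(table)

    def test_model_results_interface(self, rng):
        table = _long_table(rng.normal(size=(5, 4, 5)))
        res = tf.RmAnova(table).fit()
        assert res.n_subjects == 5
        assert res.interaction.effect == "measure:segment"
        frame = res.to_frame()
        assert set(frame.columns) == {"effect", "F", "df_num", "df_den", "p"}
        assert "F(12,48)" in res.summary()


def _oracle_fdr(p, q):
    """Exhaustive evaluation of the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestFdrBh:
    def test_single_small_p_significant(self):
        reject, adjusted = tf.fdr_bh([0.01], 0.05)
        assert reject[0] and adjusted[0] == pytest.approx(0.01)

    def test_hand_step_up_case(self):
        # 0.04 > 3*0.05/4 = 0.0375 -> only the two smallest rejected
        reject, _ = tf.fdr_bh([0.01, 0.02, 0.04, 0.5], 0.05)
        assert list(reject) == [True, True, False, False]

    def test_all_ones_nothing_significant(self):
        reject, adjusted = tf.fdr_bh([1.0, 1.0, 1.0], 0.05)
        assert not reject.any() and np.all(adjusted == 1.0)

    def test_empty_input(self):
        reject, adjusted = tf.fdr_bh([], 0.05)
        assert reject.size == 0 and adjusted.size == 0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_exhaustive_definition(self, p, q):
        reject, _ = tf.fdr_bh(p, q)
        np.testing.assert_array_equal(reject, _oracle_fdr(p, q))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests
        reject, adjusted = tf.fdr_bh(p, 0.05)
        sm_reject, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, sm_reject)
        np.testing.assert_allclose(adjusted, sm_adj, atol=1e-12)


class TestPairedT:
    def test_hand_computed_value(self):
        # differences [1, 1, 2]: mean 4/3, sd 1/sqrt(3) -> t = 4, df = 2
        t, df, p = tf.paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 1.0])
        assert t == pytest.approx(4.0, abs=1e-10)
        assert df == 2
        assert 0 < p < 1

    def test_agrees_with_scipy(self, rng):
        from scipy.stats import ttest_rel
        x, y = rng.normal(size=(2, 12))
        t, df, p = tf.paired_t(x, y)
        ref = ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_shift_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(tf.ZeroVarianceError):
            tf.paired_t(x + 2.0, x)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=(2, 10))
        t_xy, _, p_xy = tf.paired_t(x, y)
        t_yx, _, p_yx = tf.paired_t(y, x)
        assert t_xy == pytest.approx(-t_yx) and p_xy == pytest.approx(p_yx)


def _gradient_table(rng, n=16, seeds=4, segments=5, slopes=None, noise=1.0):
    rows = []
    slopes = slopes or {}
    for i in range(n):
        for j in range(seeds):
            name = f"seed{j}"
            base = rng.normal(scale=0.2)
            for s in range(1, segments + 1):
                val = (slopes.get(name, 0.0) * (s - 1) + base
                       + noise * rng.normal())
                rows.append((f"s{i:02d}", name, s, val))
    return pd.DataFrame(rows, columns=["subject", "measure", "segment",
                                       "value"])


class TestGradientHierarchy:
    def test_opposing_gradients_cascade_to_stage3(self, rng):
        slopes = {"seed0": 0.5, "seed1": -0.5}
        table = _gradient_table(rng, slopes=slopes, noise=0.3)
        report = tf.hierarchical_gradient_test({"SUB": table}, q=0.05)
        reg = report.regions["SUB"]
        assert reg.significant
        assert {"seed0", "seed1"} <= set(reg.significant_seeds)
        pair = reg.pairwise_interactions[("seed0", "seed1")]
        assert pair.p < 0.05
        assert reg.seed_slope_signs["seed0"] == 1
        assert reg.seed_slope_signs["seed1"] == -1

    def test_null_tables_rarely_significant(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            tables = {"SUB": _gradient_table(rng, n=8, noise=1.0),
                      "CA1": _gradient_table(rng, n=8, segments=3, noise=1.0)}
            report = tf.hierarchical_gradient_test(tables, q=0.05)
            if any(r.significant for r in report.regions.values()):
                hits += 1
        assert hits / n_seeds <= 0.10

    def test_stage2_skipped_when_stage1_null(self, rng):
        table = _gradient_table(rng, noise=1.0)
        report = tf.hierarchical_gradient_test({"SUB": table}, q=1e-12)
        reg = report.regions["SUB"]
        assert not reg.significant
        assert reg.seed_main_effects == {}
        assert any("skipped" in d for d in report.decisions)

    def test_single_seed_rejected(self, rng):
        table = _gradient_table(rng, seeds=1)
        with pytest.raises(tf.InvalidInputError, match="2 seeds"):
            tf.hierarchical_gradient_test({"SUB": table})

    def test_report_roundtrips_to_dict(self, rng):
        import json
        table = _gradient_table(rng, slopes={"seed0": 0.5}, noise=0.3)
        report = tf.hierarchical_gradient_test({"SUB": table})
        blob = json.dumps(report.to_dict())
        assert "interaction" in blob


def _content_table(rng, n=16, segments=5, scene_boost=None):
    rows = []
    scene_boost = scene_boost or {}
    for i in range(n):
        for s in range(1, segments + 1):
            base = rng.normal(scale=0.2)
            rows.append((f"s{i:02d}", "scene",
                         s, base + scene_boost.get(s, 0.0) + rng.normal()))
            rows.append((f"s{i:02d}", "object", s, base + rng.normal()))
    return pd.DataFrame(rows, columns=["subject", "condition", "segment",
                                       "value"])


class TestContentBias:
    def test_distal_boost_flags_distal_segments_only(self, rng):
        table = _content_table(rng, n=24, scene_boost={4: 2.0, 5: 2.0})
        report = tf.content_bias_test(table, q=0.05)
        assert report.interaction_significant
        assert set(report.scene_biased_units) == {"4", "5"}

    def test_identical_conditions_give_zero_f_and_no_posthoc(self, rng):
        table = _content_table(rng)
        wide = table[table.condition == "scene"].copy()
        wide["condition"] = "object"
        both = pd.concat([table[table.condition == "scene"], wide])
        report = tf.content_bias_test(both, q=0.05)
        assert report.interaction.F == 0.0
        assert report.post_hoc == []

    def test_wrong_conditions_rejected(self, rng):
        table = _content_table(rng)
        table.loc[table.condition == "object", "condition"] = "baseline"
        with pytest.raises(tf.InvalidInputError, match="scene and object"):
            tf.content_bias_test(table)
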