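"""Cross-validation, concordance accounting, Fisher's exact test and
per-gene differential tests."""

import dataclasses
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import beready as br
from beready.evaluation_stats import _stratified_folds
from beready.panel_io import REFERENCE_CLASSES


# ---------------------------------------------------------------------------
# Fisher's exact (lower tail)
# ---------------------------------------------------------------------------

def fisher_lower_exact(a, b, c, d):
    """Independent oracle: exact rational hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, r1)
    total = Fraction(0)
    for i in range(max(0, r1 + c1 - n), a + 1):
        total += Fraction(comb(c1, i) * comb(n - c1, r1 - i), denom)
    return total


class TestFisherLower:
    def test_reported_group_comparison(self):
        # displaced WOI: 1/57 in validation vs 7/44 in the RIF group
        p = br.fisher_lower([[1, 56], [7, 37]])
        assert round(p, 3) == pytest.approx(0.012, abs=0.0005)

    def test_identical_proportions(self):
        assert br.fisher_lower([[0, 10], [0, 10]]) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        assert br.fisher_lower([[0, 5], [5, 0]]) == pytest.approx(1 / 252)

    def test_all_zero_table_degenerates_to_one(self, caplog):
        with caplog.at_level("WARNING"):
            assert br.fisher_lower([[0, 0], [0, 0]]) == 1.0

    def test_matches_exact_enumeration_all_small_margins(self):
        """Every 2x2 table with total N <= 30, against exact rational
        hypergeometric enumeration."""
        for n in range(1, 31):
            for r1 in range(n + 1):
                for c1 in range(n + 1):
                    lo = max(0, r1 + c1 - n)
                    hi = min(r1, c1)
                    for a in range(lo, hi + 1):
                        t = [[a, r1 - a], [c1 - a, n - r1 - (c1 - a)]]
                        got = br.fisher_lower(t)
                        want = float(fisher_lower_exact(*t[0], *t[1]))
                        assert got == pytest.approx(want, abs=1e-12), t


# ---------------------------------------------------------------------------
# Concordance accounting
# ---------------------------------------------------------------------------

class TestConcordance:
    def test_validation_cohort_table(self):
        tab = br.concordance_from_table({
            "ESE": {"pre-receptive": 26},
            "MSE": {"pre-receptive": 1, "early-receptive": 6, "receptive": 19},
            "LSE": {"post-receptive": 5},
        })
        assert (tab.n, tab.concordant, tab.displaced) == (57, 56, 1)
        assert round(tab.concordance_pct, 1) == 98.2
        assert round(tab.displaced_pct, 1) == 1.8
        assert round(tab.in_range_shift_pct, 1) == 23.1  # 6/26 at MSE

    def test_rif_cohort_table(self):
        tab = br.concordance_from_table({
            "MSE": {"pre-receptive": 3, "early-receptive": 8, "receptive": 29,
                    "late-receptive": 0, "post-receptive": 4},
        })
        assert tab.displaced == 7
        assert round(tab.displaced_pct, 1) == 15.9
        assert round(tab.in_range_shift_pct, 1) == 18.2

    def test_all_concordant(self):
        tab = br.evaluate_concordance(
            ["pre-receptive"] * 3 + ["receptive"] * 3 + ["post-receptive"] * 3,
            ["ESE"] * 3 + ["MSE"] * 3 + ["LSE"] * 3,
        )
        assert tab.concordance_pct == 100.0
        assert tab.displaced == 0

    def test_unknown_phase_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            tab = br.evaluate_concordance(
                ["receptive", "receptive"], ["MSE", "PE?"])
        assert tab.n == 1
        assert tab.excluded == 1

    def test_displaced_is_subset_of_discordant(self):
        tab = br.concordance_from_table({
            "ESE": {"pre-receptive": 5, "early-receptive": 1, "receptive": 2},
            "MSE": {"pre-receptive": 1, "receptive": 5},
            "LSE": {"post-receptive": 2, "late-receptive": 1},
        })
        assert tab.concordant + (tab.n - tab.concordant) == tab.n
        assert tab.displaced <= tab.n - tab.concordant


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

class TestCrossValidation:
    def test_folds_partition_and_stratify(self):
        labels = np.array(["a"] * 30 + ["b"] * 15 + ["c"] * 10)
        rng = np.random.default_rng(9)
        folds = _stratified_folds(labels, 5, rng, ["a", "b", "c"])
        assert len(folds) == 55
        assert set(folds) == set(range(5))
        for f in range(5):
            assert set(labels[folds == f]) == {"a", "b", "c"}

    def test_separated_clusters_reach_perfect_macro_accuracy(
            self, md_config, md_counts):
        m, _ = md_counts
        res = br.crossvalidate(m, md_config.panel.housekeeper_ids,
                               n_repeats=5, seed=21)
        assert res.macro_accuracy == 1.0
        assert res.micro_accuracy == 1.0
        assert set(res.per_class_recall) == set(REFERENCE_CLASSES)

    def test_fold_assignments_cover_all_samples(self, md_config, md_counts):
        m, _ = md_counts
        res = br.crossvalidate(m, md_config.panel.housekeeper_ids,
                               n_repeats=2, seed=22)
        for folds in res.fold_assignments:
            assert len(folds) == len(m.sample_ids)
            assert sorted(set(folds)) == list(range(5))

    def test_split_model_differs_from_full_model(self, md_config, md_counts):
        """No-leakage guard: a model fitted on a training split must not
        equal the full-data model (scaling and centroids are refitted)."""
        m, _ = md_counts
        hk = md_config.panel.housekeeper_ids
        full = br.fit_reference(m, hk, seed=1)
        split = br.fit_reference(m.subset(m.sample_ids[::2]), hk, seed=1)
        assert not np.allclose(full.scaling.center, split.scaling.center)

    def test_too_few_samples_per_class_instructive_error(self, md_config):
        cfg = dataclasses.replace(
            md_config, n_per_phase={"PE": 4, "ESE": 4, "MSE": 6, "LSE": 4})
        m, _ = br.simulate_counts(cfg, seed=2)
        with pytest.raises(ValueError, match="fold"):
            br.crossvalidate(m, md_config.panel.housekeeper_ids, seed=1)


# ---------------------------------------------------------------------------
# Differential tests
# ---------------------------------------------------------------------------

def _shifted_log_matrix(md_config, seed):
    m, truth = br.simulate_counts(md_config, seed=seed)
    nm = br.normalize_housekeepers(m, md_config.panel.housekeeper_ids)
    return br.shifted_log(nm), truth


class TestDeTest:
    def test_identical_groups_give_t_zero_p_one(self):
        vals = pd.DataFrame({"g": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                            index=list("abcdef"))
        nm = br.NormalizedMatrix(vals, ("h",), "shifted-log")
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=list("abcdef"))
        res = br.de_test(nm, groups)
        assert res.loc["g", "t"] == 0.0
        assert res.loc["g", "p"] == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.normal(size=(10, 72)),
                            columns=[f"g{i}" for i in range(72)])
        nm = br.NormalizedMatrix(vals, ("h",), "shifted-log")
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=vals.index)
        res = br.de_test(nm, groups, correction="bonferroni")
        expected = np.minimum(res["p"] * 72, 1.0)
        assert np.allclose(res["p_adj"], expected)

    def test_null_simulation_rarely_significant_after_bonferroni(self, md_config):
        """Split each phase-balanced null cohort in two arbitrary halves:
        no gene should survive Bonferroni in (almost) any seed."""
        hits = 0
        for seed in range(10):
            nm, _ = _shifted_log_matrix(md_config, 300 + seed)
            idx = nm.values.index
            groups = pd.Series(np.where(np.arange(len(idx)) % 2 == 0, "A", "B"),
                               index=idx)
            res = br.de_test(nm, groups)
            hits += int(res["significant"].sum() == 0)
        assert hits >= 9

    def test_planted_effect_detected(self, md_config):
        nm, _ = _shifted_log_matrix(md_config, 44)
        vals = nm.values.copy()
        idx = vals.index
        groups = pd.Series(np.where(np.arange(len(idx)) % 2 == 0, "A", "B"),
                           index=idx)
        vals.loc[groups == "B", "RB01"] += 5.0
        nm2 = br.NormalizedMatrix(vals, nm.housekeeper_ids, "shifted-log")
        res = br.de_test(nm2, groups)
        assert res.loc["RB01", "significant"]


class TestAnovaInteraction:
    def test_null_interaction_p_values_uniform(self, md_config):
        """Purely additive phase+condition effects: interaction p-values
        should look U(0,1) (KS test not significant at alpha = 0.01)."""
        nm, truth = _shifted_log_matrix(md_config, 55)
        rng = np.random.default_rng(56)
        cond = pd.Series(rng.choice(["healthy", "pcos"], size=len(nm.values)),
                         index=nm.values.index)
        vals = nm.values + np.where(cond == "pcos", 0.3, 0.0)[:, None]
        nm2 = br.NormalizedMatrix(pd.DataFrame(vals, index=nm.values.index,
                                               columns=nm.values.columns),
                                  nm.housekeeper_ids, "shifted-log")
        res = br.anova_interaction(nm2, truth.phase, cond)
        ks = stats.kstest(res["p_interaction"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_interaction_detected(self, md_config):
        nm, truth = _shifted_log_matrix(md_config, 57)
        rng = np.random.default_rng(58)
        cond = pd.Series(rng.choice(["healthy", "pcos"], size=len(nm.values)),
                         index=nm.values.index)
        vals = nm.values.copy()
        cell = (truth.phase == "MSE") & (cond == "pcos")
        sd = vals["RB02"].std()
        vals.loc[cell, "RB02"] += 5 * sd
        nm2 = br.NormalizedMatrix(vals, nm.housekeeper_ids, "shifted-log")
        res = br.anova_interaction(nm2, truth.phase, cond)
        assert res.loc["RB02", "p_interaction"] < 0.001

    def test_duplicating_observations_sharpens_p(self):
        rng = np.random.default_rng(60)
        n = 24
        f1 = pd.Series(np.repeat(["p1", "p2"], n // 2))
        f2 = pd.Series(np.tile(["x", "y"], n // 2))
        y = rng.normal(size=n) + 0.8 * ((f1 == "p2") & (f2 == "y"))
        vals = pd.DataFrame({"g": y})
        nm = br.NormalizedMatrix(vals, ("h",), "shifted-log")
        res1 = br.anova_interaction(nm, f1, f2)
        dup = pd.concat([vals, vals], ignore_index=True)
        nm2 = br.NormalizedMatrix(dup, ("h",), "shifted-log")
        res2 = br.anova_interaction(
            nm2, pd.concat([f1, f1], ignore_index=True),
            pd.concat([f2, f2], ignore_index=True))
        assert res2.loc["g", "p_interaction"] < res1.loc["g", "p_interaction"]

    def test_empty_cell_skips_gene_with_warning(self, caplog):
        vals = pd.DataFrame({"g": [1.0, 2.0, 3.0, 4.0]})
        nm = br.NormalizedMatrix(vals, ("h",), "shifted-log")
        f1 = pd.Series(["a", "a", "b", "b"])
        f2 = pd.Series(["x", "x", "x", "x"])  # cell (a,y),(b,y) never observed
        f2[3] = "y"
        with caplog.at_level("WARNING"), pytest.raises(ValueError):
            br.anova_interaction(nm, f1, f2)
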