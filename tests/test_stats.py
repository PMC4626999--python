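"""Rank tests, Holm correction and the feature screening grid."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (bonferroni_reject, exact_mannwhitney_p,
                      holm_adjusted_reference, holm_reference)
from ppgstress import holm_bonferroni, mann_whitney_p, screen_features


class TestMannWhitney:
    def test_worked_example_most_extreme_split(self):
        assert mann_whitney_p([1.0, 2.0], [3.0, 4.0]) == pytest.approx(2.0 / 6.0)

    def test_identical_samples_give_p_one(self):
        assert mann_whitney_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=9) + 0.5
        assert mann_whitney_p(np.exp(x), np.exp(y)) == pytest.approx(
            mann_whitney_p(x, y), rel=1e-12)

    def test_exact_path_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            n, m = rng.integers(2, 7, size=2)
            x, y = rng.normal(size=int(n)), rng.normal(size=int(m))
            assert mann_whitney_p(x, y) == pytest.approx(
                exact_mannwhitney_p(x, y), abs=1e-12)

    def test_approximation_close_to_exact_above_cutover(self, rng):
        # combined n = 13 forces the normal approximation
        for _ in range(10):
            x, y = rng.normal(size=7), rng.normal(size=6)
            assert mann_whitney_p(x, y) == pytest.approx(
                exact_mannwhitney_p(x, y), abs=0.05)

    def test_paired_variant_detects_consistent_shift(self, rng):
        x = rng.normal(size=15)
        y = x + 1.0
        assert mann_whitney_p(x, y, paired=True) < 0.01
        assert mann_whitney_p(x, x, paired=True) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_p([], [1.0])


class TestHolm:
    def test_single_p_reduces_to_uncorrected(self):
        reject, adj = holm_bonferroni([0.04], alpha=0.05)
        assert reject[0]
        assert adj[0] == pytest.approx(0.04)

    def test_two_p_step_down_example(self):
        reject, _ = holm_bonferroni([0.01, 0.04], alpha=0.05)
        assert reject.tolist() == [True, True]

    def test_all_p_one_rejects_nothing(self):
        reject, _ = holm_bonferroni(np.ones(10))
        assert not reject.any()

    def test_family_at_half_bonferroni_level_fully_rejected(self):
        m = 17
        reject, _ = holm_bonferroni(np.full(m, 0.05 / (2 * m)), alpha=0.05)
        assert reject.all()

    def test_matches_definition_reference_on_random_vectors(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, size=m)
            reject, adj = holm_bonferroni(p)
            np.testing.assert_array_equal(reject, holm_reference(p))
            np.testing.assert_allclose(adj, holm_adjusted_reference(p), rtol=1e-12)

    def test_never_less_powerful_than_bonferroni(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(2, 60)))
            holm, _ = holm_bonferroni(p)
            assert holm.sum() >= bonferroni_reject(p).sum()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.0, 0.5])
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])


def _toy_feature_table(rng, n_subjects=10, orders=range(21), shift_cell=None,
                       shift=0.0):
    """Tidy feature table with standard-normal cells, optionally shifted."""
    rows = []
    for sid in range(n_subjects):
        for cond in ("BE", "E1", "E2", "E3"):
            for feature in ("energy", "entropy"):
                for status in ("unfiltered", "filtered"):
                    for order in orders:
                        v = rng.normal()
                        if (cond != "BE" and shift_cell ==
                                (feature, status, order)):
                            v += shift
                        rows.append((f"S{sid:03d}", cond, feature, status,
                                     order, v))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "feature",
                                       "status", "order", "value"])


class TestScreening:
    def test_identical_feature_column_gives_p_one(self, rng):
        table = _toy_feature_table(rng, orders=range(3))
        cell = (table.feature == "energy") & (table.status == "filtered") \
            & (table.order == 0)
        table.loc[cell, "value"] = 7.0
        res = screen_features(table)
        row = res.table[(res.table.feature == "energy")
                        & (res.table.status == "filtered")
                        & (res.table.order == 0)].iloc[0]
        assert row["p1"] == row["p2"] == row["p3"] == 1.0

    def test_injected_separation_ranks_below_family_median(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            table = _toy_feature_table(
                rng, shift_cell=("entropy", "filtered", 7), shift=2.5)
            res = screen_features(table)
            t = res.table
            target = t[(t.feature == "entropy") & (t.status == "filtered")
                       & (t.order == 7)]["p_mean"].iloc[0]
            hits += target < t["p_mean"].median()
        assert hits >= 4

    def test_full_grid_family_is_252(self, rng):
        res = screen_features(_toy_feature_table(rng))
        assert res.family_size == 252
        assert len(res.table) == 84

    def test_family_240_excludes_order_zero(self, rng):
        table = _toy_feature_table(rng)
        res = screen_features(table, family=240)
        assert res.family_size == 240
        # order-0 rows can never be Holm-rejected in the restricted family
        zero = res.table[res.table.order == 0]
        assert not zero[["holm1", "holm2", "holm3"]].to_numpy().any()

    def test_rejections_form_prefix_of_sorted_p(self, rng):
        table = _toy_feature_table(rng, shift_cell=("energy", "filtered", 2),
                                   shift=4.0)
        res = screen_features(table)
        long = res.table.melt(id_vars=["feature", "status", "order"],
                              value_vars=["p1", "p2", "p3"], value_name="p")
        holm = res.table.melt(id_vars=["feature", "status", "order"],
                              value_vars=["holm1", "holm2", "holm3"],
                              value_name="rej")
        df = long.assign(rej=holm["rej"].to_numpy()).sort_values("p")
        rej = df["rej"].to_numpy()
        if rej.any():
            last = np.max(np.flatnonzero(rej))
            assert rej[:last + 1].all()

    def test_missing_condition_is_named(self, rng):
        table = _toy_feature_table(rng, orders=range(2))
        with pytest.raises(ValueError, match="BE"):
            screen_features(table[table.condition != "BE"])
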