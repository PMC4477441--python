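import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cilioprior.screen_stats import (
    BinnedScores,
    bin_by_evidence,
    benchmark_flagged_fraction,
    hypergeom_enrichment,
    jonckheere_terpstra,
    precision_recall_curve,
    roc_auc,
    wilcoxon_one_tailed,
)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_three_of_four_concordant(self):
        assert roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(
        st.lists(st.floats(-10, 10), min_size=4, max_size=40),
        st.integers(0, 2**30),
    )
    @settings(max_examples=60, deadline=None)
    def test_negation_symmetry(self, scores, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=len(scores))
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        a = roc_auc(scores, labels)
        b = roc_auc([-s for s in scores], labels)
        assert math.isclose(a + b, 1.0, abs_tol=1e-12)


class TestPrecisionRecall:
    def test_perfect_classifier_precision_one_at_every_recall(self):
        curve = precision_recall_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        best = curve.groupby("recall")["precision"].max()
        assert (best[best.index > 0] == 1.0).all()
        assert 1.0 in best.index

    def test_lowest_threshold_recall_one_precision_prevalence(self):
        curve = precision_recall_curve([0.9, 0.5, 0.1], [1, 0, 0])
        last = curve.iloc[-1]
        assert last["recall"] == 1.0
        assert last["precision"] == pytest.approx(1 / 3)

    def test_direct_counting(self):
        curve = precision_recall_curve([0.9, 0.5, 0.1], [1, 0, 0])
        at = curve[curve["threshold"] == 0.9].iloc[0]
        assert at["precision"] == 1.0 and at["recall"] == 1.0

    def test_recall_non_decreasing(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        curve = precision_recall_curve(scores, labels)
        assert (curve["recall"].diff().dropna() >= 0).all()


def brute_force_rank_sum_p(x, y):
    """Oracle: enumerate every assignment of pooled values to the x slots."""
    pooled = list(x) + list(y)
    n_x = len(x)
    obs = sum(
        sum(1.0 if xi > v else 0.5 if xi == v else 0.0 for v in pooled) - 0.5
        for xi in x
    )

    def stat(subset):
        chosen = [pooled[i] for i in subset]
        return sum(
            sum(1.0 if c > v else 0.5 if c == v else 0.0 for v in pooled) - 0.5
            for c in chosen
        )

    combos = list(itertools.combinations(range(len(pooled)), n_x))
    hits = sum(stat(c) >= obs - 1e-9 for c in combos)
    return hits / len(combos)


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        assert wilcoxon_one_tailed([3, 4, 5], [1, 2]) == pytest.approx(0.1)

    def test_strong_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, size=50)
        y = rng.normal(0, 1, size=50)
        assert wilcoxon_one_tailed(x, y) < 1e-6

    def test_identical_samples_large_p(self):
        assert wilcoxon_one_tailed([1, 2, 3], [1, 2, 3]) >= 0.4

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_one_tailed([], [1.0])

    def test_less_alternative_swaps_samples(self):
        assert wilcoxon_one_tailed([1, 2], [3, 4, 5], alternative="less") == (
            wilcoxon_one_tailed([3, 4, 5], [1, 2], alternative="greater")
        )

    @given(st.integers(0, 2**30))
    @settings(max_examples=30, deadline=None)
    def test_exact_path_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_x, n_y = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        pooled = rng.permutation(np.arange(1.0, n_x + n_y + 1))
        x, y = pooled[:n_x], pooled[n_x:]
        assert wilcoxon_one_tailed(x, y) == pytest.approx(
            brute_force_rank_sum_p(x, y)
        )

    def test_exact_and_approx_agree_near_switchover(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pooled = rng.permutation(np.arange(1.0, 13.0))
            x, y = pooled[:6], pooled[6:]
            exact = wilcoxon_one_tailed(x, y, exact_max_n=12)
            approx = wilcoxon_one_tailed(x, y, exact_max_n=0)
            assert abs(exact - approx) < 0.02


def brute_force_jt_p(groups):
    """Oracle: permute pooled values over the group layout."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]

    def jt(gs):
        total = 0.0
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                for a in gs[i]:
                    for b in gs[j]:
                        total += 1.0 if a < b else 0.5 if a == b else 0.0
        return total

    obs = jt(groups)
    hits = 0
    count = 0
    for perm in itertools.permutations(range(len(pooled))):
        arranged = []
        k = 0
        for s in sizes:
            arranged.append([pooled[i] for i in perm[k : k + s]])
            k += s
        count += 1
        hits += jt(arranged) >= obs - 1e-9
    return hits / count


class TestJonckheereTerpstra:
    def test_exact_two_bin_example(self):
        binned = BinnedScores(labels=("0", "1"), values=((1, 2), (3, 4)))
        stat, p = jonckheere_terpstra(binned)
        assert stat == 4.0
        assert p == pytest.approx(1 / 6)

    def test_decreasing_groups_large_p(self):
        binned = BinnedScores(labels=("0", "1"), values=((5, 6), (1, 2)))
        _, p = jonckheere_terpstra(binned)
        assert p >= 0.5

    def test_within_bin_permutation_invariant(self):
        a = BinnedScores(labels=("0", "1"), values=((1, 3, 2), (5, 4)))
        b = BinnedScores(labels=("0", "1"), values=((2, 1, 3), (4, 5)))
        assert jonckheere_terpstra(a)[0] == jonckheere_terpstra(b)[0]

    def test_fewer_than_two_bins_raises(self):
        binned = BinnedScores(labels=("0", "1"), values=((1, 2), ()))
        with pytest.raises(ValueError):
            jonckheere_terpstra(binned)

    def test_two_bin_statistic_is_mann_whitney_u(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(size=7)
            binned = BinnedScores(
                labels=("0", "1"), values=(tuple(a), tuple(b))
            )
            stat, _ = jonckheere_terpstra(binned, exact_max_n=0)
            u = sum(
                1.0 if x < y else 0.5 if x == y else 0.0
                for x in a
                for y in b
            )
            assert stat == pytest.approx(u)

    @given(st.integers(0, 2**30))
    @settings(max_examples=15, deadline=None)
    def test_exact_path_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = [int(rng.integers(2, 4)) for _ in range(2)]
        groups = [list(rng.integers(0, 5, size=s).astype(float)) for s in sizes]
        binned = BinnedScores(
            labels=tuple(map(str, range(len(groups)))),
            values=tuple(tuple(g) for g in groups),
        )
        _, p = jonckheere_terpstra(binned)
        assert p == pytest.approx(brute_force_jt_p(groups))

    def test_exact_and_approx_agree_near_switchover(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            pooled = rng.permutation(np.arange(1.0, 11.0))
            groups = [pooled[:3], pooled[3:6], pooled[6:]]
            binned = BinnedScores(
                labels=("0", "1", "2"), values=tuple(tuple(g) for g in groups)
            )
            _, exact = jonckheere_terpstra(binned, exact_max_n=10)
            _, approx = jonckheere_terpstra(binned, exact_max_n=0)
            assert abs(exact - approx) < 0.02


def score_table(scores: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame({"gene": list(scores), "score": list(scores.values())})


def evidence(noe_any: dict[str, int], noe_human=None) -> pd.DataFrame:
    noe_human = noe_human or {g: 0 for g in noe_any}
    return pd.DataFrame(
        {
            "gene": list(noe_any),
            "noe_any": list(noe_any.values()),
            "noe_human": [noe_human[g] for g in noe_any],
        }
    )


class TestBinByEvidence:
    def test_terminal_bin_collects_high_counts(self):
        binned = bin_by_evidence(
            score_table({"A": 0.1, "B": 0.2, "C": 0.3}),
            evidence({"A": 0, "B": 3, "C": 12}),
        )
        by_label = dict(zip(binned.labels, binned.values))
        assert by_label["0"] == (0.1,)
        assert by_label["3"] == (0.2,)
        assert by_label[">=8"] == (0.3,)

    def test_human_only_uses_human_column(self):
        binned = bin_by_evidence(
            score_table({"A": 0.5}),
            evidence({"A": 9}, {"A": 1}),
            exact_counts=(0, 1, 2, 3),
            terminal_min=4,
            human_only=True,
        )
        assert dict(zip(binned.labels, binned.values))["1"] == (0.5,)

    def test_counts_partition_non_excluded_genes(self):
        table = score_table({f"g{i}": i / 10 for i in range(10)})
        ev = evidence({f"g{i}": i for i in range(10)})
        binned = bin_by_evidence(table, ev, exclude_genes={"g0", "g1"})
        assert sum(binned.counts) == 8

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError):
            bin_by_evidence(
                score_table({"A": 0.5}),
                evidence({"A": 1}),
                exact_counts=(0, 1, 2),
                terminal_min=2,
            )


class TestBenchmarkFraction:
    def test_subset_gives_one(self):
        assert benchmark_flagged_fraction(None, {"A", "B"}, {"A", "B", "C"}) == 1.0

    def test_disjoint_gives_zero(self):
        assert benchmark_flagged_fraction(None, {"A"}, {"B"}) == 0.0

    def test_counting(self):
        held = {f"h{i}" for i in range(12)}
        selected = {"h0", "h1", "h2", "x"}
        assert benchmark_flagged_fraction(None, held, selected) == 0.25

    def test_empty_held_out_raises(self):
        with pytest.raises(ValueError):
            benchmark_flagged_fraction(None, set(), {"A"})


class TestHypergeomEnrichment:
    BACKGROUND = [f"g{i}" for i in range(20)]

    def test_hand_summed_tail(self):
        # background 20, set 5, query 5, overlap 3 -> 1126/15504
        query = {"g0", "g1", "g2", "g10", "g11"}
        sets = {"S": ["g0", "g1", "g2", "g3", "g4"]}
        res = hypergeom_enrichment(
            query, sets, self.BACKGROUND, min_overlap=3, fdr_max=1.01
        )
        assert res[0].p_value == pytest.approx(1126 / 15504)

    def test_min_overlap_filter(self):
        query = {"g0", "g1", "g10", "g11", "g12"}
        sets = {"S": ["g0", "g1", "g2", "g3", "g4"]}
        assert (
            hypergeom_enrichment(
                query, sets, self.BACKGROUND, min_overlap=3, fdr_max=1.01
            )
            == []
        )

    def test_size_filters(self):
        big_bg = [f"g{i}" for i in range(500)]
        query = set(big_bg[:10])
        sets = {"big": big_bg[:450], "small": big_bg[:3]}
        assert hypergeom_enrichment(query, sets, big_bg, fdr_max=1.01) == []

    def test_query_outside_background_raises(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"zzz"}, {}, self.BACKGROUND)

    def test_bh_fdr_non_decreasing_in_p(self):
        rng = np.random.default_rng(3)
        bg = [f"g{i}" for i in range(60)]
        query = set(bg[:15])
        sets = {
            f"S{k}": list(rng.choice(bg, size=10, replace=False))
            for k in range(12)
        }
        res = hypergeom_enrichment(
            query, sets, bg, min_set=5, max_set=60, min_overlap=0, fdr_max=1.01
        )
        ordered = sorted(res, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in ordered]
        assert fdrs == sorted(fdrs)
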