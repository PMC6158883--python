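"""The weighted running-sum statistic and its gene-permutation null."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from moonpipe.datatypes import OverallScores, ValidationError
from moonpipe.enrichment import (
    enrichment_score,
    percentile_membership,
    permutation_pvalue,
    rank_genes,
    running_sum,
)


def naive_es(ranked_scores: pd.Series, members: set[str], exponent: float) -> float:
    """Literal running-sum oracle: hits add |s|^p / sum, misses 1/(N-|S|)."""
    values = ranked_scores.to_numpy(dtype=float)
    mask = np.array([g in members for g in ranked_scores.index])
    weights = np.abs(values) ** exponent
    hit_total = weights[mask].sum()
    walk, best = 0.0, 0.0
    for i in range(len(values)):
        if mask[i]:
            walk += weights[i] / hit_total
        else:
            walk -= 1.0 / (len(values) - mask.sum())
        if abs(walk) > abs(best) or (abs(walk) == abs(best) and walk > best):
            best = walk
    return best


def exhaustive_pvalue(scores: pd.Series, members: set[str], exponent: float) -> float:
    """Exact two-sided p by enumerating every same-size gene subset."""
    ranked = rank_genes(scores)
    observed = abs(enrichment_score(ranked, members, exponent=exponent))
    k = len(members & set(scores.index))
    es_all = [
        abs(enrichment_score(ranked, set(combo), exponent=exponent))
        for combo in itertools.combinations(scores.index, k)
    ]
    tol = 1e-12  # fp noise must not flip the >= comparison
    return sum(1 for e in es_all if e >= observed - tol) / len(es_all)


class TestRanking:
    def test_descending_order(self):
        ranked = rank_genes(pd.Series({"A": 2.0, "B": 1.0}))
        assert list(ranked.index) == ["A", "B"]

    def test_ties_break_lexicographically(self):
        ranked = rank_genes(pd.Series({"B": 1.0, "A": 1.0}))
        assert list(ranked.index) == ["A", "B"]

    def test_random_vector_matches_stable_sort(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(
            rng.integers(0, 5, 30).astype(float), index=[f"g{i:02d}" for i in range(30)]
        )
        expected = sorted(scores.index, key=lambda g: (-scores[g], g))
        assert list(rank_genes(scores).index) == expected

    def test_non_finite_score_names_gene(self):
        with pytest.raises(ValidationError, match="gX"):
            rank_genes(pd.Series({"gA": 1.0, "gX": np.nan}))


class TestEnrichmentScore:
    def test_top_gene_unweighted_is_one(self):
        scores = pd.Series({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        assert enrichment_score(rank_genes(scores), {"a"}, exponent=0.0) == 1.0

    def test_bottom_gene_unweighted_is_minus_one(self):
        scores = pd.Series({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        assert enrichment_score(rank_genes(scores), {"d"}, exponent=0.0) == -1.0

    def test_worked_four_gene_example(self):
        # walk: -1/3, then -1/3 + 3/3 = 2/3, then 1/3, then 0
        scores = pd.Series({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        es, walk = running_sum(rank_genes(scores), {"b"}, exponent=1.0)
        assert es == pytest.approx(2.0 / 3.0)
        assert walk[:2] == pytest.approx([-1.0 / 3.0, 2.0 / 3.0])

    def test_disjoint_and_covering_sets_rejected(self):
        scores = pd.Series({"a": 2.0, "b": 1.0})
        with pytest.raises(ValidationError):
            enrichment_score(rank_genes(scores), {"zz"})
        with pytest.raises(ValidationError):
            enrichment_score(rank_genes(scores), {"a", "b"})

    @pytest.mark.parametrize("exponent", [0.0, 1.0, 2.0])
    def test_matches_naive_oracle_on_random_inputs(self, exponent):
        rng = np.random.default_rng(int(exponent * 10) + 1)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            scores = pd.Series(
                rng.standard_normal(n), index=[f"g{i:03d}" for i in range(n)]
            )
            k = int(rng.integers(1, n))
            members = set(rng.choice(scores.index, size=k, replace=False))
            ranked = rank_genes(scores)
            assert enrichment_score(ranked, members, exponent) == pytest.approx(
                naive_es(ranked, members, exponent)
            )

    def test_rank_only_mode_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(
            rng.standard_normal(25), index=[f"g{i:02d}" for i in range(25)]
        )
        members = set(scores.index[:7])
        transformed = pd.Series(np.exp(scores) + 10.0, index=scores.index)
        es_a = enrichment_score(rank_genes(scores), members, exponent=0.0)
        es_b = enrichment_score(rank_genes(transformed), members, exponent=0.0)
        assert es_a == es_b

    def test_rank_only_antisymmetry(self):
        # reversing the ranking negates the unweighted ES
        rng = np.random.default_rng(4)
        values = np.sort(rng.standard_normal(21))[::-1]  # strictly decreasing
        scores = pd.Series(values, index=[f"g{i:02d}" for i in range(21)])
        members = set(scores.index[[0, 3, 9]])
        forward = enrichment_score(rank_genes(scores), members, exponent=0.0)
        backward = enrichment_score(rank_genes(-scores), members, exponent=0.0)
        assert backward == pytest.approx(-forward)

    def test_agrees_with_independent_gsea_implementation(self):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(0)
        scores = pd.Series(
            rng.standard_normal(60), index=[f"g{i:02d}" for i in range(60)]
        )
        members = list(scores.sample(8, random_state=1).index)
        ranked = rank_genes(scores)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gseapy.prerank(
                rnk=ranked.reset_index(),
                gene_sets={"S": members},
                permutation_num=5,
                outdir=None,
                seed=0,
                min_size=1,
                max_size=100,
                weight=1.0,
                no_plot=True,
            )
        theirs = float(res.res2d.loc[res.res2d["Term"] == "S", "ES"].iloc[0])
        ours = enrichment_score(ranked, set(members), exponent=1.0)
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestEnrichmentScoreProperties:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _case(values, k):
        scores = pd.Series(values, index=[f"g{i:03d}" for i in range(len(values))])
        members = set(scores.index[:k])
        return rank_genes(scores), members

    @given(
        values=st.lists(
            st.floats(-50, 50, allow_nan=False, width=32), min_size=3, max_size=40
        ),
        k_frac=st.floats(0.01, 0.99),
        exponent=st.sampled_from([0.0, 1.0, 2.0]),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_es_bounded_and_matches_naive_oracle(self, values, k_frac, exponent):
        k = max(1, min(len(values) - 1, int(k_frac * len(values))))
        ranked, members = self._case(values, k)
        es = enrichment_score(ranked, members, exponent=exponent)
        assert -1.0 - 1e-9 <= es <= 1.0 + 1e-9
        assert es == pytest.approx(naive_es(ranked, members, exponent), abs=1e-9)


class TestPermutationPvalue:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        scores = pd.Series(
            rng.standard_normal(50), index=[f"g{i:02d}" for i in range(50)]
        )
        members = set(scores.index[:6])
        a = permutation_pvalue(scores, members, n_perm=500, seed=123)
        b = permutation_pvalue(scores, members, n_perm=500, seed=123)
        assert (a.es, a.p_value, a.null_mean, a.null_sd) == (
            b.es,
            b.p_value,
            b.null_mean,
            b.null_sd,
        )
        assert a.leading_edge == b.leading_edge

    def test_single_top_gene_enumeration(self):
        # exhaustive oracle over the 10 single-gene sets: |ES| = 1 for the
        # top AND the bottom gene, so two-sided p -> 2/10, one-sided -> 1/10
        scores = pd.Series(
            {f"g{i}": 10.0 - i for i in range(10)}, index=[f"g{i}" for i in range(10)]
        )
        two = permutation_pvalue(scores, {"g0"}, n_perm=20_000, seed=0, exponent=0.0)
        one = permutation_pvalue(
            scores, {"g0"}, n_perm=20_000, seed=0, exponent=0.0, alternative="greater"
        )
        assert two.es == 1.0
        assert two.p_value == pytest.approx(0.2, abs=0.015)
        assert one.p_value == pytest.approx(0.1, abs=0.015)

    @pytest.mark.parametrize("n,k", [(6, 2), (8, 3)])
    def test_matches_exhaustive_enumeration(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        scores = pd.Series(
            rng.standard_normal(n), index=[f"g{i}" for i in range(n)]
        )
        members = set(rng.choice(scores.index, size=k, replace=False))
        exact = exhaustive_pvalue(scores, members, exponent=1.0)
        res = permutation_pvalue(scores, members, n_perm=20_000, seed=1)
        mc_sd = np.sqrt(exact * (1 - exact) / 20_000)
        assert res.p_value == pytest.approx(exact, abs=3 * mc_sd + 1e-4)

    def test_pvalue_floor_is_one_over_nperm_plus_one(self):
        scores = pd.Series(
            {f"g{i:03d}": 100.0 - i for i in range(100)},
        )
        members = set(scores.index[:10])
        res = permutation_pvalue(scores, members, n_perm=200, seed=0)
        assert res.p_value >= 1 / 201

    def test_leading_edge_for_depleted_set_is_at_the_bottom(self):
        scores = pd.Series(
            {f"g{i:03d}": float(100 - i) for i in range(100)},
        )
        members = set(scores.index[-5:])
        res = permutation_pvalue(scores, members, n_perm=100, seed=0)
        assert res.es < 0
        assert set(res.leading_edge) <= members


class TestPercentileMembership:
    def test_set_entirely_above_quantile(self):
        scores = pd.Series(
            {**{f"lo{i:02d}": 0.0 for i in range(95)}, **{f"hi{i}": 10.0 for i in range(5)}}
        )
        count, size, above, _ = percentile_membership(
            scores, {f"hi{i}" for i in range(5)}, q=0.95
        )
        assert count == size == 5

    def test_median_split_of_symmetric_scores(self):
        n = 400
        scores = pd.Series(
            np.arange(n, dtype=float), index=[f"g{i:03d}" for i in range(n)]
        )
        members = {f"g{i:03d}" for i in range(0, n, 2)}  # every other gene
        count, size, _, _ = percentile_membership(scores, members, q=0.5)
        assert abs(count - size / 2) <= 1

    def test_zero_coverage_genes_excluded_from_universe(self):
        scores = OverallScores(
            score=pd.Series({"a": 5.0, "b": 1.0, "c": 0.0}),
            coverage=pd.Series({"a": 10, "b": 10, "c": 0}),
        )
        count, _, above, threshold = percentile_membership(scores, {"a", "c"}, q=0.5)
        # the quantile is over {a, b} only; c never counts
        assert above == ["a"]
        assert threshold == pytest.approx(3.0)

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValidationError):
            percentile_membership(pd.Series({"a": 1.0}), {"a"}, q=1.5)
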