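"""Hairpin selection, consensus signatures, connectivity and clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from moonpipe.datatypes import (
    ConsensusSignature,
    GeneSet,
    SignatureCollection,
    ValidationError,
)
from moonpipe.signatures import (
    background_distribution,
    cluster_connectivity,
    consensus_signature,
    cut_clusters,
    pairwise_connectivity,
    select_hairpins,
    signature_set_enrichment,
)
from moonpipe.simulate import gen_connectivity_signatures, gen_signatures


def make_collection(z_rows, experiments):
    """z_rows: gene -> values; experiments: (exp_id, hairpin, cell_line)."""
    ids = [e[0] for e in experiments]
    z = pd.DataFrame.from_dict(z_rows, orient="index", columns=ids).astype(float)
    ann = pd.DataFrame(
        {
            "perturbed_gene": ["T"] * len(ids),
            "hairpin_id": [e[1] for e in experiments],
            "cell_line": [e[2] for e in experiments],
        },
        index=ids,
    )
    return SignatureCollection(z=z, annotations=ann)


class TestSelectHairpins:
    def test_most_negative_target_means_selected(self):
        experiments = [(f"e{i}", f"h{i}", "A") for i in range(5)]
        col = make_collection(
            {"T": [-4.0, -3.5, -3.0, -1.0, -0.2], "G": [0.0] * 5}, experiments
        )
        assert select_hairpins(col, "T", k=3) == ["h0", "h1", "h2"]

    def test_k_all_gives_full_ordering(self):
        experiments = [(f"e{i}", f"h{i}", "A") for i in range(4)]
        col = make_collection({"T": [-1.0, -3.0, 0.5, -2.0], "G": [0.0] * 4}, experiments)
        assert select_hairpins(col, "T", k=4) == ["h1", "h3", "h0", "h2"]

    def test_mean_over_replicate_experiments(self):
        experiments = [("e1", "h1", "A"), ("e2", "h1", "B"), ("e3", "h2", "A")]
        col = make_collection({"T": [-4.0, 0.0, -1.0], "G": [0.0] * 3}, experiments)
        # h1 mean = -2.0 beats h2 = -1.0
        assert select_hairpins(col, "T", k=1) == ["h1"]

    def test_absent_target_rejected(self):
        col = make_collection({"G": [0.0]}, [("e1", "h1", "A")])
        with pytest.raises(ValidationError):
            select_hairpins(col, "T")

    def test_planted_strongest_hairpins_recovered(self, generator_config):
        collection, truth = gen_signatures(generator_config)
        chosen = select_hairpins(collection, "QUERY", k=3)
        # the planted strongest-3 hairpins are well separated from the rest
        assert set(chosen) == set(truth.payload["hairpins_by_strength"][:3])


class TestConsensus:
    def test_two_experiment_mean(self):
        col = make_collection(
            {"G1": [1.0, 3.0], "G2": [0.0, -2.0]},
            [("e1", "h1", "A"), ("e2", "h1", "B")],
        )
        consensus = consensus_signature(col, ["h1"])
        assert consensus.values["G1"] == 2.0
        assert consensus.values["G2"] == -1.0

    def test_cell_line_exclusion_removes_its_experiments(self):
        col = make_collection(
            {"G1": [1.0, 3.0, 100.0]},
            [("e1", "h1", "A"), ("e2", "h1", "B"), ("e3", "h1", "ASC")],
        )
        consensus = consensus_signature(col, ["h1"], exclude_cell_lines=["ASC"])
        assert consensus.values["G1"] == 2.0
        assert ("h1", "ASC") not in consensus.contributors

    def test_nothing_surviving_rejected(self):
        col = make_collection({"G1": [1.0]}, [("e1", "h1", "ASC")])
        with pytest.raises(ValidationError):
            consensus_signature(col, ["h1"], exclude_cell_lines=["ASC"])

    def test_matches_naive_per_gene_loop(self):
        rng = np.random.default_rng(0)
        experiments = [(f"e{i}", f"h{i % 3}", f"C{i % 4}") for i in range(12)]
        z_rows = {f"G{g}": list(rng.standard_normal(12)) for g in range(20)}
        col = make_collection(z_rows, experiments)
        consensus = consensus_signature(col, ["h0", "h2"], exclude_cell_lines=["C1"])
        keep = [
            e[0] for e in experiments if e[1] in ("h0", "h2") and e[2] != "C1"
        ]
        for gene in z_rows:
            expected = np.mean([col.z.loc[gene, e] for e in keep])
            assert consensus.values[gene] == pytest.approx(expected)

    def test_consensus_linearity_over_experiment_partition(self):
        # consensus(A u B) equals the contributor-count-weighted mean
        rng = np.random.default_rng(1)
        experiments = [(f"e{i}", "hA" if i < 3 else "hB", "X") for i in range(8)]
        z_rows = {f"G{g}": list(rng.standard_normal(8)) for g in range(10)}
        col = make_collection(z_rows, experiments)
        both = consensus_signature(col, ["hA", "hB"]).values
        a = consensus_signature(col, ["hA"]).values
        b = consensus_signature(col, ["hB"]).values
        weighted = (3 * a + 5 * b) / 8
        pd.testing.assert_series_equal(both, weighted, atol=1e-12, rtol=0)


class TestSignatureEnrichment:
    def test_planted_depletion_detected(self, generator_config):
        collection, truth = gen_signatures(generator_config)
        hairpins = select_hairpins(collection, "QUERY", k=3)
        consensus = consensus_signature(
            collection, hairpins, truth.payload["sparse_cell_lines"]
        )
        res = signature_set_enrichment(
            consensus, set(truth.payload["depleted_set"]), n_perm=2000, seed=1
        )
        assert res.es < -0.5
        assert res.p_value <= 0.001

    def test_bottom_ranked_set_is_extremal(self):
        rng = np.random.default_rng(2)
        values = pd.Series(
            rng.standard_normal(300), index=[f"g{i:03d}" for i in range(300)]
        )
        sig = ConsensusSignature(values=values)
        bottom = set(values.nsmallest(29).index)
        es_bottom = signature_set_enrichment(sig, bottom, n_perm=1, seed=0).es
        for _ in range(50):
            other = set(rng.choice(values.index, size=29, replace=False))
            es_other = signature_set_enrichment(sig, other, n_perm=1, seed=0).es
            assert es_bottom <= es_other + 1e-12


class TestBackgroundDistribution:
    def test_planted_depleted_set_ranks_first(self):
        rng = np.random.default_rng(3)
        values = pd.Series(
            rng.standard_normal(1000), index=[f"g{i:04d}" for i in range(1000)]
        )
        planted = list(rng.choice(values.index, size=29, replace=False))
        values[planted] -= 2.5
        sig = ConsensusSignature(values=values)
        sets = [GeneSet(name="planted", members=frozenset(planted))]
        for i in range(100):
            sets.append(
                GeneSet(
                    name=f"null{i:02d}",
                    members=frozenset(rng.choice(values.index, size=29, replace=False)),
                )
            )
        table = background_distribution(sig, sets, query_set_name="planted")
        assert table.iloc[0]["set"] == "planted"
        assert table.iloc[0]["rank"] == 1

    def test_single_set_collection(self):
        values = pd.Series({"a": 1.0, "b": 0.0, "c": -1.0})
        sig = ConsensusSignature(values=values)
        table = background_distribution(
            sig, [GeneSet(name="only", members=frozenset({"a"}))]
        )
        assert len(table) == 1
        assert table.iloc[0]["rank"] == 1

    def test_identical_sets_get_identical_scores(self):
        values = pd.Series({"a": 2.0, "b": 1.0, "c": 0.0, "d": -1.0})
        sig = ConsensusSignature(values=values)
        sets = [
            GeneSet(name=f"S{i}", members=frozenset({"a", "c"})) for i in range(3)
        ]
        table = background_distribution(sig, sets)
        assert table["es"].nunique() == 1

    def test_disjoint_set_skipped_with_warning(self):
        values = pd.Series({"a": 1.0, "b": -1.0})
        sig = ConsensusSignature(values=values)
        sets = [
            GeneSet(name="ok", members=frozenset({"a"})),
            GeneSet(name="alien", members=frozenset({"zz"})),
        ]
        with pytest.warns(UserWarning, match="alien"):
            table = background_distribution(sig, sets)
        assert list(table["set"]) == ["ok"]


class TestConnectivity:
    def _pair(self, n=600, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:04d}" for i in range(n)]
        a = pd.Series(rng.standard_normal(n), index=genes)
        return {
            "a": ConsensusSignature(values=a),
            "neg": ConsensusSignature(values=-a),
            "b": ConsensusSignature(values=pd.Series(rng.standard_normal(n), index=genes)),
        }

    def test_diagonal_is_hundred(self):
        table = pairwise_connectivity(self._pair(), top_n=50)
        assert (np.diag(table.to_numpy()) == 100.0).all()

    def test_negation_scores_minus_hundred(self):
        table = pairwise_connectivity(self._pair(), top_n=50)
        assert table.loc["a", "neg"] == -100.0

    def test_symmetry_and_bounds(self):
        table = pairwise_connectivity(self._pair(), top_n=50)
        assert np.allclose(table.to_numpy(), table.to_numpy().T)
        assert (table.to_numpy() <= 100.0).all() and (table.to_numpy() >= -100.0).all()

    def test_top_n_too_large_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_connectivity(self._pair(n=80), top_n=40)

    def test_within_block_exceeds_between_block(self, generator_config):
        signatures, truth = gen_connectivity_signatures(generator_config)
        table = pairwise_connectivity(signatures, top_n=150)
        blocks = truth.payload["blocks"]
        names = list(signatures)
        within, between = [], []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                (within if blocks[a] == blocks[b] else between).append(
                    table.loc[a, b]
                )
        assert min(within) > max(between)


class TestClustering:
    def test_identical_rows_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(10)
        table = pd.DataFrame(
            [base, base, rng.standard_normal(10)], index=["r1", "r2", "r3"]
        )
        order, tree = cluster_connectivity(table)
        assert tree[0, 2] == pytest.approx(0.0)
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}

    def test_planted_blocks_recovered_at_cut(self, generator_config):
        signatures, truth = gen_connectivity_signatures(generator_config)
        table = pairwise_connectivity(signatures, top_n=150)
        order, tree = cluster_connectivity(table)
        clusters = cut_clusters(tree, table.index, n_clusters=3)
        blocks = truth.payload["blocks"]
        # cluster labels must be a relabelling of the planted blocks
        mapping = {}
        for name, cluster in clusters.items():
            mapping.setdefault(cluster, set()).add(blocks[name])
        assert all(len(v) == 1 for v in mapping.values())
        assert len(mapping) == 3

    def test_row_permutation_leaves_tree_invariant(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            rng.standard_normal((6, 6)), index=list("abcdef"), columns=list("abcdef")
        )
        order1, tree1 = cluster_connectivity(table)
        perm = list(rng.permutation(table.index))
        table2 = table.loc[perm, :]
        order2, tree2 = cluster_connectivity(table2)
        # same merge heights, and same leaf partition at every cut
        assert np.allclose(np.sort(tree1[:, 2]), np.sort(tree2[:, 2]))
        for k in (2, 3):
            c1 = cut_clusters(tree1, table.index, k)
            c2 = cut_clusters(tree2, table2.index, k)
            parts1 = {frozenset(n for n in c1 if c1[n] == v) for v in set(c1.values())}
            parts2 = {frozenset(n for n in c2 if c2[n] == v) for v in set(c2.values())}
            assert parts1 == parts2

    def test_constant_row_warns_and_is_distant(self):
        table = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.2, 0.9, -0.4], [0.1, 0.8, -0.5]],
            index=["const", "x", "y"],
        )
        with pytest.warns(UserWarning, match="const"):
            order, tree = cluster_connectivity(table)
        # x and y merge before const joins
        assert {int(tree[0, 0]), int(tree[0, 1])} == {1, 2}

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            cluster_connectivity(pd.DataFrame([[1.0, 0.0]], index=["r1"]))

    def test_newick_export_parses_with_all_leaves(self):
        from io import StringIO

        from Bio import Phylo

        from moonpipe.signatures import tree_to_newick

        rng = np.random.default_rng(6)
        table = pd.DataFrame(
            rng.standard_normal((5, 5)), index=list("abcde"), columns=list("abcde")
        )
        _, tree = cluster_connectivity(table)
        newick = tree_to_newick(tree, list(table.index))
        parsed = Phylo.read(StringIO(newick), "newick")
        assert sorted(leaf.name for leaf in parsed.get_terminals()) == list("abcde")
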