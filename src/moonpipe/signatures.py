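"""Consensus knockdown signatures, connectivity scoring and clustering.

Multi-hairpin shRNA perturbation data (Level-5-style z-scores per gene per
experiment) are reduced to one consensus signature per perturbed gene:
hairpins are ranked by on-target knockdown, the strongest are kept,
experiments from unreliable cell lines are excluded, and the surviving
experiments' z-scores are averaged gene-wise.  Consensus signatures feed
the running-sum enrichment test, a CMap-style pairwise connectivity score
scaled to [-100, 100], and average-linkage/correlation clustering of the
connectivity table.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .datatypes import (
    ConsensusSignature,
    GeneSet,
    SignatureCollection,
    ValidationError,
)
from .enrichment import EnrichmentResult, enrichment_score, permutation_pvalue, rank_genes

#: connectivity magnitude conventionally treated as significant
CONNECTIVITY_THRESHOLD = 90.0


def select_hairpins(
    collection: SignatureCollection, target_gene: str, k: int = 3
) -> list[str]:
    """Hairpins with the strongest on-target knockdown.

    Hairpins are ranked by the mean z-score of the target gene over each
    hairpin's experiments, ascending (most negative = strongest
    knockdown); the top ``k`` are returned.  Ties break by hairpin id.
    """
    if target_gene not in collection.z.index:
        raise ValidationError(f"target gene {target_gene!r} not measured")
    target_z = collection.z.loc[target_gene]
    means = target_z.groupby(collection.annotations["hairpin_id"]).mean()
    order = sorted(means.index, key=lambda h: (means[h], h))
    return order[: int(k)]


def consensus_signature(
    collection: SignatureCollection,
    hairpins: Sequence[str],
    exclude_cell_lines: Sequence[str] = (),
) -> ConsensusSignature:
    """Flat gene-wise mean over the experiments of the chosen hairpins.

    Experiments from ``exclude_cell_lines`` are discarded first.  The mean
    is over experiments, not a mean of per-cell-line means.
    """
    ann = collection.annotations
    keep = ann["hairpin_id"].isin(set(hairpins)) & ~ann["cell_line"].isin(
        set(exclude_cell_lines)
    )
    if not keep.any():
        raise ValidationError("no experiments survive hairpin/cell-line filters")
    exp_ids = ann.index[keep]
    return ConsensusSignature(
        values=collection.z[exp_ids].mean(axis=1),
        contributors=[
            (ann.at[e, "hairpin_id"], ann.at[e, "cell_line"]) for e in exp_ids
        ],
        excluded_cell_lines=list(exclude_cell_lines),
    )


def signature_set_enrichment(
    signature: ConsensusSignature,
    gene_set: GeneSet | set[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    exponent: float = 1.0,
) -> EnrichmentResult:
    """Permutation enrichment of a gene set in a consensus signature."""
    return permutation_pvalue(
        signature.values, gene_set, n_perm=n_perm, seed=seed, exponent=exponent
    )


def background_distribution(
    signature: ConsensusSignature,
    set_collection: Sequence[GeneSet],
    query_set_name: str | None = None,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Enrichment scores of a whole gene-set collection on one signature.

    Returns a table (set name, size in universe, ES, ascending rank,
    percentile) sorted by ES; rank 1 is the most negatively enriched set.
    Sets disjoint from, or covering, the universe are skipped with a
    warning.
    """
    if not set_collection:
        raise ValidationError("empty gene-set collection")
    ranked = rank_genes(signature.values)
    universe = set(ranked.index)
    rows = []
    for gs in set_collection:
        overlap = len(universe & gs.members)
        if overlap == 0 or overlap == len(universe):
            warnings.warn(
                f"gene set {gs.name!r} skipped (overlap {overlap} of "
                f"{len(universe)} universe genes)",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "set": gs.name,
                "size": overlap,
                "es": enrichment_score(ranked, gs, exponent=exponent),
            }
        )
    table = pd.DataFrame(rows).sort_values(["es", "set"]).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["percentile"] = 100.0 * table["rank"] / len(table)
    if query_set_name is not None and query_set_name not in set(table["set"]):
        raise ValidationError(f"query set {query_set_name!r} was skipped or absent")
    return table


def _signature_frame(
    signatures: Mapping[str, ConsensusSignature]
) -> pd.DataFrame:
    if len(signatures) < 2:
        raise ValidationError("need >= 2 signatures for connectivity")
    frame = pd.DataFrame({name: sig.values for name, sig in signatures.items()})
    frame = frame.dropna(axis=0)
    if frame.empty:
        raise ValidationError("signatures share no gene universe")
    return frame


def pairwise_connectivity(
    signatures: Mapping[str, ConsensusSignature],
    top_n: int = 150,
    exponent: float = 0.0,
) -> pd.DataFrame:
    """CMap-style connectivity scores between consensus signatures.

    The raw similarity of signature *a* to *b* averages the enrichment
    score of *a*'s ``top_n`` most-induced genes in *b*'s ranking with the
    negated enrichment score of *a*'s ``top_n`` most-repressed genes, so a
    signature is maximally connected to itself and maximally
    anti-connected to its negation.  Raw values are percentile-normalised
    against the batch pooled with its own negation (an odd-symmetric map,
    so sign is preserved and zero maps to zero) and scaled to
    [-100, 100]; the matrix is symmetrised by averaging and the diagonal
    set to 100.  This is this package's own formulation of the
    connectivity idea; numerical identity with any online service is not
    claimed.
    """
    frame = _signature_frame(signatures)
    n_genes, names = frame.shape[0], list(frame.columns)
    if top_n >= n_genes / 2:
        raise ValidationError(
            f"top_n={top_n} must be < half the shared universe ({n_genes})"
        )
    rankings = {name: rank_genes(frame[name]) for name in names}
    tops = {name: set(rankings[name].index[:top_n]) for name in names}
    bottoms = {name: set(rankings[name].index[-top_n:]) for name in names}

    raw = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            if a == b:
                continue
            up = enrichment_score(rankings[b], tops[a], exponent=exponent)
            down = enrichment_score(rankings[b], bottoms[a], exponent=exponent)
            raw.loc[a, b] = (up - down) / 2.0

    off = raw.to_numpy()[~np.eye(len(names), dtype=bool)]
    # pool the batch with its own negation: the resulting rank map is odd,
    # so sign is preserved, 0 maps to 0 and the extremes map to +/-100
    pooled = np.unique(np.concatenate([off, -off]))
    scaled = pd.DataFrame(100.0, index=names, columns=names)
    if len(pooled) > 1:
        span = len(pooled) - 1
        for a in names:
            for b in names:
                if a == b:
                    continue
                frac = np.searchsorted(pooled, raw.loc[a, b]) / span
                scaled.loc[a, b] = 100.0 * (2.0 * frac - 1.0)
    else:  # every pair identical (necessarily raw == 0)
        scaled.loc[:, :] = 0.0
        np.fill_diagonal(scaled.to_numpy(), 100.0)
    sym = (scaled + scaled.T) / 2.0
    np.fill_diagonal(sym.to_numpy(), 100.0)
    return sym.clip(-100.0, 100.0)


def cluster_connectivity(table: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage clustering of connectivity rows on correlation distance.

    Distance between two perturbations is ``1 - Pearson(row_i, row_j)``;
    constant rows get the maximal distance 2 to every other row, with a
    warning.  Returns the leaf order and the SciPy linkage matrix.
    """
    if table.shape[0] < 2:
        raise ValidationError("need >= 2 rows to cluster")
    rows = table.to_numpy(dtype=float)
    sd = rows.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant connectivity rows {list(table.index[constant])} assigned "
            "maximal distance",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(rows)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    merge_tree = linkage(squareform(dist, checks=False), method="average")
    order = [str(table.index[i]) for i in leaves_list(merge_tree)]
    return order, merge_tree


def cut_clusters(merge_tree: np.ndarray, labels: Sequence[str], n_clusters: int) -> dict[str, int]:
    """Flat cluster assignment from a merge tree."""
    flat = fcluster(merge_tree, t=n_clusters, criterion="maxclust")
    return {str(label): int(c) for label, c in zip(labels, flat)}


def tree_to_newick(merge_tree: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a SciPy linkage matrix as a Newick string.

    Branch lengths are the height differences between a node and its
    parent merge, so the text round-trips the dendrogram geometry.
    """
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return str(labels[node])
        left, right, height = (
            int(merge_tree[node - n, 0]),
            int(merge_tree[node - n, 1]),
            float(merge_tree[node - n, 2]),
        )
        heights[node] = height
        parts = []
        for child in (left, right):
            sub = render(child)
            parts.append(f"{sub}:{height - heights[child]:.6g}")
        return "(" + ",".join(parts) + ")"

    return render(2 * n - 2) + ";"
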