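"""Network edge-count enrichment, dependency correlation screens, half-lives.

Three orthogonal lines of corroborating evidence for a shared function
between a query protein and its called interactors:

* how many physical interactions the interactor set has among itself in a
  background protein-protein interaction network, versus random same-size
  node sets;
* which genes have dependency profiles (growth effect of knockdown or
  knockout across cell lines) correlated with the query's, with
  family-wise Bonferroni control;
* where the query's protein half-life sits in the distribution of
  metabolic enzymes quantified in each cell line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HalfLifeTable, ValidationError


@dataclass
class EdgeEnrichmentResult:
    """Observed vs expected within-set edge counts under a resampling null."""

    observed_edges: int
    expected_edges: float
    fold: float
    p_value: float
    n_draws: int
    set_size: int


def edge_enrichment(
    network: nx.Graph,
    node_set: set[str],
    n_draws: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> EdgeEnrichmentResult:
    """Edge-count enrichment of a node set in a background network.

    The null resamples ``n_draws`` uniform node subsets of the same size
    from the background (no degree matching) and counts induced edges;
    ``p = (1 + #{null >= observed}) / (n_draws + 1)``.  Nodes absent from
    the background are dropped with a warning.
    """
    nodes = sorted(network.nodes)
    present = sorted(n for n in node_set if n in network)
    missing = sorted(node_set - set(present))
    if missing:
        warnings.warn(f"nodes absent from background dropped: {missing}", stacklevel=2)
    k = len(present)
    if k < 2:
        raise ValidationError("need >= 2 set nodes present in the background")
    if len(nodes) < k:
        raise ValidationError("background smaller than the node set")

    adjacency = nx.to_numpy_array(network, nodelist=nodes, weight=None).astype(bool)
    index = {n: i for i, n in enumerate(nodes)}
    ids = np.array([index[n] for n in present])
    observed = int(adjacency[np.ix_(ids, ids)].sum() // 2)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_draws)
    chunk = max(1, min(n_draws, 4096))
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        u = rng.random((b, len(nodes)))
        draw = np.argpartition(u, k - 1, axis=1)[:, :k]
        sub = adjacency[draw[:, :, None], draw[:, None, :]]
        null[done : done + b] = sub.sum(axis=(1, 2)) / 2
        done += b

    expected = float(null.mean())
    if expected > 0:
        fold = observed / expected
    else:
        fold = float("inf") if observed > 0 else 0.0
    p = (1 + int((null >= observed).sum())) / (n_draws + 1)
    return EdgeEnrichmentResult(
        observed_edges=observed,
        expected_edges=expected,
        fold=fold,
        p_value=p,
        n_draws=n_draws,
        set_size=k,
    )


def degree_stratified_edge_enrichment(
    network: nx.Graph,
    node_set: set[str],
    n_draws: int = 100_000,
    n_strata: int = 5,
    seed: int | np.random.Generator | None = None,
) -> EdgeEnrichmentResult:
    """Edge-count enrichment with degree-stratified resampling.

    Background nodes are binned into ``n_strata`` degree quantile bins and
    each null draw samples, per bin, as many nodes as the observed set has
    there.  A sterner null than uniform resampling when the set is rich in
    hubs.
    """
    nodes = sorted(network.nodes)
    present = sorted(n for n in node_set if n in network)
    if len(present) < 2:
        raise ValidationError("need >= 2 set nodes present in the background")
    degrees = np.array([network.degree(n) for n in nodes], dtype=float)
    edges = np.quantile(degrees, np.linspace(0, 1, n_strata + 1)[1:-1])
    bins = np.searchsorted(edges, degrees, side="right")
    index = {n: i for i, n in enumerate(nodes)}
    set_bins = bins[[index[n] for n in present]]

    adjacency = nx.to_numpy_array(network, nodelist=nodes, weight=None).astype(bool)
    ids = np.array([index[n] for n in present])
    observed = int(adjacency[np.ix_(ids, ids)].sum() // 2)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bin_members = [np.where(bins == b)[0] for b in range(n_strata)]
    bin_counts = [int((set_bins == b).sum()) for b in range(n_strata)]
    null = np.empty(n_draws)
    for i in range(n_draws):
        draw = np.concatenate(
            [
                rng.choice(bin_members[b], size=c, replace=False)
                for b, c in enumerate(bin_counts)
                if c
            ]
        )
        null[i] = adjacency[np.ix_(draw, draw)].sum() / 2
    expected = float(null.mean())
    fold = observed / expected if expected > 0 else (float("inf") if observed else 0.0)
    p = (1 + int((null >= observed).sum())) / (n_draws + 1)
    return EdgeEnrichmentResult(
        observed_edges=observed,
        expected_edges=expected,
        fold=fold,
        p_value=p,
        n_draws=n_draws,
        set_size=len(present),
    )


def correlate_dependencies(
    dependency: pd.DataFrame, query_gene: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of every gene's dependency profile with the query's.

    Correlations are pairwise-complete; two-sided p-values come from the
    exact t transform ``t = r sqrt((n-2)/(1-r^2))``; Bonferroni correction
    is over the genes actually tested (>= 3 paired observations and
    non-degenerate variance).  Returns a table (r, n, p_raw, p_bonferroni,
    significant) sorted by descending r; excluded genes are recorded in
    ``table.attrs["n_excluded"]``.
    """
    if query_gene not in dependency.index:
        raise ValidationError(f"query gene {query_gene!r} not in dependency matrix")
    query = dependency.loc[query_gene].to_numpy(dtype=float)
    if np.isfinite(query).sum() < 3:
        raise ValidationError("query profile has < 3 non-missing entries")
    if np.nanstd(query) == 0:
        raise ValidationError("query profile has zero variance")

    values = dependency.to_numpy(dtype=float)
    qmask = np.isfinite(query)
    mask = np.isfinite(values) & qmask[None, :]
    x = np.where(mask, values, 0.0)
    q = np.where(qmask, query, 0.0)
    n = mask.sum(axis=1)
    sx, sq = x.sum(axis=1), mask @ q
    sxx, sqq, sxq = (x * x).sum(axis=1), mask @ (q * q), x @ q
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (n * sxx - sx**2) * (n * sqq - sq**2)
        r = np.where(var > 0, (n * sxq - sx * sq) / np.sqrt(np.maximum(var, 0)), np.nan)
    r = np.clip(r, -1.0, 1.0)

    tested = (n >= 3) & np.isfinite(r)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, np.finfo(float).tiny))
    p_raw = np.where(tested, 2 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1)), np.nan)
    m = int(tested.sum())
    p_bonf = np.minimum(p_raw * m, 1.0)

    table = pd.DataFrame(
        {
            "r": r,
            "n": n,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "significant": (p_raw <= alpha / m) & tested,
        },
        index=dependency.index,
    )
    table = table[tested].sort_values(["r", "p_raw"], ascending=[False, True])
    table.attrs["n_excluded"] = int(len(dependency) - m)
    table.attrs["n_tested"] = m
    table.attrs["alpha"] = alpha
    return table


def halflife_percentile(
    table: HalfLifeTable, query_protein: str
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Percentile of the query's half-life among quantified enzymes.

    For each cell line where the query is measured, the percentile is the
    mean rank (ascending, ties averaged) of the query among enzymes
    quantified in that cell line, as a percentage of their count.  Also
    returns, per cell line, the cumulative-frequency curve points
    ``(half_life_hours, cumulative_fraction)`` over the enzyme background.
    """
    hl = table.half_life_hours
    if query_protein not in hl.index:
        raise ValidationError(f"query {query_protein!r} absent from half-life table")
    if hl.loc[query_protein].notna().sum() == 0:
        raise ValidationError(f"query {query_protein!r} not measured in any cell line")
    enzymes = sorted(set(table.enzyme_ids) | {query_protein})
    background = hl.loc[[e for e in enzymes if e in hl.index]]

    rows = []
    curves: dict[str, pd.DataFrame] = {}
    for cell_line in hl.columns:
        values = background[cell_line].dropna()
        if query_protein not in values.index:
            rows.append(
                {"cell_line": cell_line, "percentile": np.nan, "n_enzymes": len(values)}
            )
            continue
        ranks = stats.rankdata(values.to_numpy())
        pct = 100.0 * ranks[list(values.index).index(query_protein)] / len(values)
        rows.append(
            {"cell_line": cell_line, "percentile": pct, "n_enzymes": len(values)}
        )
        ordered = np.sort(values.to_numpy())
        curves[cell_line] = pd.DataFrame(
            {
                "half_life_hours": ordered,
                "cumulative_fraction": np.arange(1, len(ordered) + 1) / len(ordered),
            }
        )
    return pd.DataFrame(rows), curves
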