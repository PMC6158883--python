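"""Meta-analytic co-expression of a query gene across an expression compendium.

For every dataset d in a compendium, a binary indicator marks each gene g
as co-expressed with the query (x = 1) or not (x = 0), with missingness
tracked separately; summing indicators over datasets gives each gene an
overall co-expression score, and datasets are ranked for a gene set by the
weighted sum of those scores over the set's indicator column.

Datasets are analysed as deposited — no normalisation is applied here; the
indicator is either a Pearson-correlation threshold against the query
(default) or membership in the query's cluster under average-linkage
hierarchical clustering on correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import (
    CoexpressionMatrix,
    ExpressionDataset,
    GeneSet,
    OverallScores,
    ValidationError,
)


@dataclass(frozen=True)
class CoexpressionParams:
    """Settings for indicator construction and dataset ranking.

    ``correlation_threshold`` is one-sided (positive correlations only):
    the indicator is meant to capture co-induction of the query with its
    partners, not anti-correlation.
    """

    min_samples: int = 6
    indicator_rule: str = "correlation_threshold"  # or "co_cluster"
    correlation_threshold: float = 0.7
    top_k_datasets: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold < 1:
            raise ValidationError("correlation threshold must be in (0, 1)")
        if self.min_samples < 3:
            raise ValidationError("min_samples must be >= 3")
        if self.indicator_rule not in ("correlation_threshold", "co_cluster"):
            raise ValidationError(f"unknown indicator rule {self.indicator_rule!r}")


def collapse_features(dataset: ExpressionDataset) -> ExpressionDataset:
    """Collapse features (probes) to genes, keeping the highest-mean probe.

    For each gene the surviving feature is the one with the highest mean
    signal across samples (missing values ignored); ties go to the
    lexicographically smallest feature id.  Genes whose features are all
    entirely missing are dropped with a warning.
    """
    mapped = [f for f in dataset.values.index if f in dataset.feature_to_gene]
    if not mapped:
        raise ValidationError(f"dataset {dataset.dataset_id!r}: no mapped features")
    targets = [dataset.feature_to_gene[f] for f in mapped]
    if len(set(targets)) == len(targets):  # one probe per gene: rename only
        values = dataset.values.loc[mapped].copy()
        values.index = targets
        empty = values.index[values.isna().all(axis=1)]
        if len(empty):
            warnings.warn(
                f"dataset {dataset.dataset_id!r}: dropped genes with all-missing "
                f"features: {sorted(map(str, empty))}",
                stacklevel=2,
            )
            values = values.drop(index=empty)
        values = values.loc[sorted(values.index)]
        return ExpressionDataset(
            dataset_id=dataset.dataset_id,
            values=values,
            feature_to_gene={g: g for g in values.index},
        )
    values = dataset.values.loc[mapped]
    means = values.mean(axis=1, skipna=True)
    best: dict[str, str] = {}
    dropped: list[str] = []
    genes = pd.Series({f: dataset.feature_to_gene[f] for f in mapped})
    for gene, feats in genes.groupby(genes).groups.items():
        m = means.loc[feats].dropna()
        if m.empty:
            dropped.append(str(gene))
            continue
        top = m.max()
        best[str(gene)] = min(f for f in m.index if m[f] == top)
    if dropped:
        warnings.warn(
            f"dataset {dataset.dataset_id!r}: dropped genes with all-missing "
            f"features: {sorted(dropped)}",
            stacklevel=2,
        )
    collapsed = values.loc[[best[g] for g in sorted(best)]]
    collapsed.index = sorted(best)
    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        values=collapsed,
        feature_to_gene={g: g for g in collapsed.index},
    )


def _pairwise_pearson(values: np.ndarray, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson r of each row of ``values`` against ``query``.

    Returns (r, n_pairs); r is NaN where undefined (zero variance or
    fewer than 2 paired values).
    """
    qmask = np.isfinite(query)
    mask = np.isfinite(values) & qmask[None, :]
    x = np.where(mask, values, 0.0)
    q = np.where(qmask, query, 0.0)
    n = mask.sum(axis=1)
    sx = x.sum(axis=1)
    sq = mask @ q
    sxx = (x * x).sum(axis=1)
    sqq = mask @ (q * q)
    sxq = x @ q
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxq - sx * sq
        var = (n * sxx - sx**2) * (n * sqq - sq**2)
        r = np.where(var > 0, cov / np.sqrt(np.maximum(var, 0)), np.nan)
    r = np.where(n >= 2, r, np.nan)
    return np.clip(r, -1.0, 1.0), n


def coexpression_indicator(
    dataset: ExpressionDataset,
    query_gene: str,
    params: CoexpressionParams | None = None,
) -> pd.Series:
    """Binary co-expression indicator column for one gene-level dataset.

    Returns a Series over the dataset's genes: 1.0 for co-expressed with
    the query, 0.0 for measured but not co-expressed, NaN for genes with
    fewer than ``min_samples`` paired observations.  If the query itself is
    absent, under-measured or constant, the whole column is NaN (the
    dataset is uninformative) and a warning is issued.
    """
    params = params or CoexpressionParams()
    values = dataset.values
    column = pd.Series(np.nan, index=values.index, name=dataset.dataset_id)
    if query_gene not in values.index:
        warnings.warn(
            f"dataset {dataset.dataset_id!r}: query {query_gene!r} not measured",
            stacklevel=2,
        )
        return column
    query = values.loc[query_gene].to_numpy(dtype=float)
    if np.isfinite(query).sum() < params.min_samples or np.nanstd(query) == 0:
        warnings.warn(
            f"dataset {dataset.dataset_id!r}: query under-measured or constant; "
            "column flagged missing",
            stacklevel=2,
        )
        return column

    r, n = _pairwise_pearson(values.to_numpy(dtype=float), query)
    enough = n >= params.min_samples
    if params.indicator_rule == "correlation_threshold":
        with np.errstate(invalid="ignore"):
            ind = (r >= params.correlation_threshold).astype(float)
        ind[~enough | ~np.isfinite(r)] = np.nan
    else:
        ind = _co_cluster_indicator(values, query_gene, enough, params)
    column[:] = ind
    column[values.index == query_gene] = 1.0
    return column


def _co_cluster_indicator(
    values: pd.DataFrame, query_gene: str, enough: np.ndarray, params: CoexpressionParams
) -> np.ndarray:
    """Alternative rule: 1 for genes in the query's cluster.

    Average-linkage agglomeration on correlation distance (1 - r), cut at
    distance ``1 - correlation_threshold``.
    """
    ind = np.full(len(values), np.nan)
    usable = enough & (values.std(axis=1, skipna=True).to_numpy() > 0)
    usable_idx = np.where(usable)[0]
    sub = values.iloc[usable_idx]
    if len(sub) < 2 or query_gene not in sub.index:
        return ind
    corr = np.corrcoef(np.nan_to_num(sub.to_numpy(dtype=float)))
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    labels = fcluster(
        linkage(squareform(dist, checks=False), method="average"),
        t=1.0 - params.correlation_threshold,
        criterion="distance",
    )
    query_label = labels[list(sub.index).index(query_gene)]
    ind[usable_idx] = (labels == query_label).astype(float)
    ind[~usable & enough] = 0.0
    return ind


def build_coexpression_matrix(
    datasets: Iterable[ExpressionDataset],
    query_gene: str,
    params: CoexpressionParams | None = None,
    collapse: bool = True,
) -> CoexpressionMatrix:
    """Indicator matrix (genes x datasets) over a compendium."""
    params = params or CoexpressionParams()
    columns = []
    for ds in datasets:
        gene_level = collapse_features(ds) if collapse else ds
        columns.append(coexpression_indicator(gene_level, query_gene, params))
    if not columns:
        raise ValidationError("empty compendium")
    matrix = pd.concat(columns, axis=1)
    return CoexpressionMatrix(indicator=matrix, query_gene=query_gene)


def overall_scores(matrix: CoexpressionMatrix) -> OverallScores:
    """Sum the indicators over datasets; track per-gene coverage.

    Missing entries contribute nothing to the score but are visible as
    reduced coverage, so downstream analyses can exclude genes that were
    rarely measured.
    """
    x = matrix.indicator
    return OverallScores(
        score=x.sum(axis=1, skipna=True).astype(float),
        coverage=x.notna().sum(axis=1).astype(int),
    )


def rank_datasets(
    matrix: CoexpressionMatrix,
    scores: OverallScores,
    gene_set: GeneSet | Sequence[str],
    k: int | None = None,
) -> pd.DataFrame:
    """Rank datasets for a gene set by the weighted indicator sum.

    Dataset d's score is the sum over set members g of
    ``overall_score(g) * x(g, d)`` with missing indicators contributing 0;
    datasets are returned in descending score order (ties by dataset id),
    truncated to the top ``k``.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else set(gene_set)
    genes = [g for g in matrix.indicator.index if g in members]
    if not genes:
        raise ValidationError("gene set shares no genes with the indicator matrix")
    x = matrix.indicator.loc[genes].fillna(0.0)
    w = scores.score.loc[genes]
    s = x.mul(w, axis=0).sum(axis=0)
    table = (
        pd.DataFrame({"dataset_id": s.index, "score": s.to_numpy(dtype=float)})
        .sort_values(["score", "dataset_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    if k is not None:
        if k > len(table):
            warnings.warn(
                f"requested top {k} of {len(table)} datasets; returning all",
                stacklevel=2,
            )
        table = table.head(k)
    return table
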