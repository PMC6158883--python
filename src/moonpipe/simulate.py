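"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one of the real input classes — controlled IP-MS
peptide tables, an expression compendium, Level-5-style knockdown
z-scores, dependency matrices, half-life tables and a background
interaction network — at desk scale, with the signal planted explicitly
and returned as a machine-readable truth object.  All randomness flows
from a single seed through named substreams, so adding one generator never
perturbs another's draws and identical configurations yield identical
data.

The planted world is coherent across generators: the query gene's true
IP-MS interactors are the same 29 genes that form the planted
co-expression module, the depleted set in the knockdown signatures and
the dense subgraph of the background network, so the full pipeline can be
exercised end to end against a single ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionDataset,
    GeneSet,
    HalfLifeTable,
    SignatureCollection,
    ConsensusSignature,
    ValidationError,
)

#: query gene/protein identifier used across all generated inputs
QUERY_ID = "QUERY"

# substream tags: one per generator, so draws are independent of call order
_STREAMS = {
    "ipms": 1,
    "compendium": 2,
    "signatures": 3,
    "connectivity": 4,
    "dependency": 5,
    "halflife": 6,
    "network": 7,
}


def gene_ids(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic world, with desk-scale defaults.

    The defaults mirror the study design the pipeline is built for: a
    12-sample IP-MS experiment (wild-type: 4 + 2 bait-antibody and 2
    isotype samples; knockout: 2 + 2), a 29-member true interactor set,
    a 200-dataset compendium with 20 planted co-expression datasets, and
    a 5-hairpin x 9-cell-line knockdown grid over 12,000 genes plus two
    sparse cell lines meant to be excluded.
    """

    seed: int = 0

    # IP-MS
    n_proteins: int = 200
    n_true_interactors: int = 29
    detect_prob_true: float = 0.9
    detect_prob_background: float = 0.3
    peptide_rate_true: float = 3.0
    peptide_rate_background: float = 1.0
    peptide_rate_bait: float = 10.0
    replicates: tuple[tuple[str, str, int], ...] = (
        ("WT", "bait-1", 4),
        ("WT", "bait-2", 2),
        ("WT", "isotype", 2),
        ("KO", "bait-1", 2),
        ("KO", "bait-2", 2),
    )

    # expression compendium
    n_datasets: int = 200
    n_planted_datasets: int = 20
    n_genes_compendium: int = 500
    n_samples_per_dataset: int = 20
    module_size: int = 30  # including the query
    module_correlation: float = 0.9
    multi_probe_fraction: float = 0.0
    probe_offset: float = 2.0

    # knockdown signatures
    n_genes_signatures: int = 12_000
    n_hairpins: int = 5
    n_cell_lines: int = 9
    sparse_cell_lines: tuple[str, ...] = ("CLX1", "CLX2")
    depleted_set_size: int = 29
    depletion_depth: float = 1.5
    on_target_depths: tuple[float, ...] = (4.0, 3.5, 3.0, 1.0, 0.5)

    # connectivity blocks
    n_perturbations: int = 9
    n_blocks: int = 3
    block_correlation: float = 0.8
    n_genes_connectivity: int = 2_000

    # dependency screens
    n_genes_dependency: int = 1_000
    n_cell_lines_dependency: int = 300
    dependency_block_size: int = 10
    dependency_correlation: float = 0.6
    dependency_missing_fraction: float = 0.05

    # half-life tables
    n_enzymes: int = 600
    halflife_log_mean: float = float(np.log(40.0))
    halflife_log_sd: float = 0.8
    query_halflife_quantile: float = 0.05
    halflife_cell_lines: tuple[str, ...] = ("HL1", "HL2", "HL3")
    halflife_missing_fraction: float = 0.05

    # background network
    n_network_nodes: int = 500
    edge_probability: float = 0.02
    planted_clique: bool = True

    def __post_init__(self) -> None:
        for name in (
            "detect_prob_true",
            "detect_prob_background",
            "multi_probe_fraction",
            "dependency_missing_fraction",
            "halflife_missing_fraction",
            "edge_probability",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("module_correlation", "dependency_correlation", "block_correlation"):
            if not -1 < getattr(self, name) < 1:
                raise ValidationError(f"{name} must be in (-1, 1)")
        if self.depletion_depth < 0:
            raise ValidationError("depletion_depth must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class Truth:
    """Planted ground truth emitted alongside each generated input."""

    kind: str
    payload: dict[str, Any] = field(default_factory=dict)


def interactor_gene_set(config: GeneratorConfig) -> GeneSet:
    """The planted true-interactor set shared by all generators."""
    return GeneSet(
        name="planted_interactors",
        members=frozenset(gene_ids(config.n_true_interactors)),
        description="planted true interactors of the query",
    )


# ---------------------------------------------------------------------------
# IP-MS


def gen_ipms(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, Truth]:
    """Controlled IP-MS peptide evidence with planted interactors.

    True interactors are detected only in wild-type bait-antibody samples
    (per-sample probability ``detect_prob_true``, count 1 + Poisson);
    background binders stick to everything, including knockout and isotype
    samples, with probability ``detect_prob_background`` per sample; the
    bait itself is detected in every wild-type bait sample and nowhere
    else.
    """
    rng = config.rng("ipms")
    samples = []
    for genotype, antibody, n_rep in config.replicates:
        for rep in range(1, n_rep + 1):
            samples.append(
                {
                    "sample_id": f"{genotype}_{antibody}_r{rep}",
                    "genotype": genotype,
                    "antibody": antibody,
                    "replicate": rep,
                }
            )
    annotations = pd.DataFrame(samples)
    wt_bait = [
        s["sample_id"]
        for s in samples
        if s["genotype"] == "WT" and s["antibody"] != "isotype"
    ]

    ids = gene_ids(config.n_proteins - 1)
    true_ids = ids[: config.n_true_interactors]
    background_ids = ids[config.n_true_interactors :]
    all_sample_ids = [s["sample_id"] for s in samples]

    def detections(protein_ids, sample_ids, prob, rate):
        detected = rng.random((len(protein_ids), len(sample_ids))) < prob
        counts = 1 + rng.poisson(rate, size=detected.shape)
        rows, cols = np.nonzero(detected)
        return pd.DataFrame(
            {
                "protein_id": np.asarray(protein_ids, dtype=object)[rows],
                "sample_id": np.asarray(sample_ids, dtype=object)[cols],
                "unique_peptides": counts[rows, cols],
            }
        )

    bait = detections([QUERY_ID], wt_bait, 1.0, config.peptide_rate_bait)
    true_part = detections(true_ids, wt_bait, config.detect_prob_true, config.peptide_rate_true)
    bg_part = detections(
        background_ids, all_sample_ids, config.detect_prob_background,
        config.peptide_rate_background,
    )
    evidence = pd.concat([bait, true_part, bg_part], ignore_index=True)[
        ["protein_id", "sample_id", "unique_peptides"]
    ]
    truth = Truth(
        kind="ipms",
        payload={
            "bait": QUERY_ID,
            "true_interactors": true_ids,
            "background_binders": background_ids,
        },
    )
    return evidence, annotations, truth


# ---------------------------------------------------------------------------
# expression compendium


def gen_compendium(
    config: GeneratorConfig,
) -> tuple[list[ExpressionDataset], Truth]:
    """Expression compendium with a co-expression module planted in some datasets.

    In each planted dataset a latent factor drives the module genes (the
    query plus its 29 planted partners) with loading sqrt(rho), giving
    pairwise population correlation ``module_correlation`` between any two
    module genes; all other genes, and every gene in non-planted datasets,
    are independent noise.  With ``multi_probe_fraction > 0`` a fraction of
    genes get a second, attenuated probe with a lower mean, to exercise
    probe collapsing.
    """
    rng = config.rng("compendium")
    genes = [QUERY_ID] + gene_ids(config.n_genes_compendium - 1)
    module = [QUERY_ID] + gene_ids(config.module_size - 1)
    loading = np.sqrt(config.module_correlation)
    planted_ids = [f"DS{i:04d}" for i in range(1, config.n_planted_datasets + 1)]
    all_ids = [f"DS{i:04d}" for i in range(1, config.n_datasets + 1)]

    n_multi = int(round(config.multi_probe_fraction * len(genes)))
    multi_genes = list(rng.choice(genes, size=n_multi, replace=False)) if n_multi else []

    gene_pos = {g: i for i, g in enumerate(genes)}
    module_idx = np.array([gene_pos[g] for g in module])
    n = config.n_samples_per_dataset
    datasets = []
    for ds_id in all_ids:
        profiles = rng.standard_normal((len(genes), n))
        if ds_id in planted_ids:
            factor = rng.standard_normal(n)
            profiles[module_idx] = loading * factor + np.sqrt(
                1 - loading**2
            ) * rng.standard_normal((len(module), n))
        features = [f"{g}_p1" for g in genes]
        feature_map = dict(zip(features, genes))
        rows = profiles + config.probe_offset
        if multi_genes:
            weak_idx = np.array([gene_pos[g] for g in multi_genes])
            weak = 0.2 * profiles[weak_idx] + rng.standard_normal((len(multi_genes), n))
            features = features + [f"{g}_p2" for g in multi_genes]
            feature_map.update({f"{g}_p2": g for g in multi_genes})
            rows = np.vstack([rows, weak])
        values = pd.DataFrame(
            rows, index=features, columns=[f"s{j + 1}" for j in range(n)]
        )
        datasets.append(
            ExpressionDataset(dataset_id=ds_id, values=values, feature_to_gene=feature_map)
        )
    truth = Truth(
        kind="compendium",
        payload={
            "query": QUERY_ID,
            "module_genes": module,
            "planted_datasets": planted_ids,
            "multi_probe_genes": sorted(map(str, multi_genes)),
            "preferred_probe_suffix": "_p1",
        },
    )
    return datasets, truth


# ---------------------------------------------------------------------------
# knockdown signatures


def gen_signatures(config: GeneratorConfig) -> tuple[SignatureCollection, Truth]:
    """Level-5-style knockdown z-scores with planted on-target and set effects.

    Base z-scores are standard normal.  Each hairpin h subtracts its own
    on-target depth from the query gene's row in its experiments; the
    planted depleted set (the query's true interactors) loses
    ``depletion_depth`` in every experiment.  The main grid covers
    ``n_hairpins x n_cell_lines``; each sparse cell line contributes a
    single extra experiment (hairpin 1) and is meant to be excluded for
    having too few replicates.
    """
    if len(config.on_target_depths) != config.n_hairpins:
        raise ValidationError("need one on-target depth per hairpin")
    rng = config.rng("signatures")
    genes = [QUERY_ID] + gene_ids(config.n_genes_signatures - 1)
    depleted = gene_ids(config.depleted_set_size)
    hairpins = [f"HP{i}" for i in range(1, config.n_hairpins + 1)]
    cell_lines = [f"CL{i}" for i in range(1, config.n_cell_lines + 1)]

    exp_ids, ann_rows = [], []
    for hp in hairpins:
        for cl in cell_lines:
            exp_ids.append(f"{hp}_{cl}")
            ann_rows.append({"perturbed_gene": QUERY_ID, "hairpin_id": hp, "cell_line": cl})
    for cl in config.sparse_cell_lines:
        exp_ids.append(f"{hairpins[0]}_{cl}")
        ann_rows.append({"perturbed_gene": QUERY_ID, "hairpin_id": hairpins[0], "cell_line": cl})

    z = rng.standard_normal((len(genes), len(exp_ids)))
    frame = pd.DataFrame(z, index=genes, columns=exp_ids)
    annotations = pd.DataFrame(ann_rows, index=exp_ids)
    for hp, depth in zip(hairpins, config.on_target_depths):
        cols = annotations.index[annotations["hairpin_id"] == hp]
        frame.loc[QUERY_ID, cols] -= depth
    frame.loc[depleted] -= config.depletion_depth

    order = np.argsort(-np.asarray(config.on_target_depths))
    truth = Truth(
        kind="signatures",
        payload={
            "query": QUERY_ID,
            "depleted_set": depleted,
            "depletion_depth": config.depletion_depth,
            "hairpins_by_strength": [hairpins[i] for i in order],
            "sparse_cell_lines": list(config.sparse_cell_lines),
        },
    )
    return SignatureCollection(z=frame, annotations=annotations), truth


def gen_connectivity_signatures(
    config: GeneratorConfig,
) -> tuple[dict[str, ConsensusSignature], Truth]:
    """Consensus signatures in correlated blocks, for connectivity tests.

    Perturbations are assigned round-robin to ``n_blocks`` blocks; within
    a block every signature shares a latent component with loading
    sqrt(``block_correlation``), so within-block pairs are more similar
    than between-block pairs.
    """
    rng = config.rng("connectivity")
    genes = gene_ids(config.n_genes_connectivity)
    loading = np.sqrt(config.block_correlation)
    latents = rng.standard_normal((config.n_blocks, len(genes)))
    signatures: dict[str, ConsensusSignature] = {}
    blocks: dict[str, int] = {}
    for i in range(config.n_perturbations):
        block = i % config.n_blocks
        values = loading * latents[block] + np.sqrt(1 - loading**2) * rng.standard_normal(
            len(genes)
        )
        name = f"PERT{i + 1:02d}"
        signatures[name] = ConsensusSignature(values=pd.Series(values, index=genes))
        blocks[name] = block
    return signatures, Truth(kind="connectivity", payload={"blocks": blocks})


# ---------------------------------------------------------------------------
# dependency, half-life, network


def gen_dependency(config: GeneratorConfig) -> tuple[pd.DataFrame, Truth]:
    """Dependency matrix with a correlated block around the query.

    The query and the first ``dependency_block_size - 1`` genes load on a
    shared per-cell-line factor with loading sqrt(rho_dep), so their
    pairwise population correlation is ``dependency_correlation``; all
    other genes are independent.  A fraction of entries is set missing.
    """
    rng = config.rng("dependency")
    genes = [QUERY_ID] + gene_ids(config.n_genes_dependency - 1)
    block = [QUERY_ID] + gene_ids(config.dependency_block_size - 1)
    n_cl = config.n_cell_lines_dependency
    loading = np.sqrt(config.dependency_correlation)
    factor = rng.standard_normal(n_cl)
    values = rng.standard_normal((len(genes), n_cl))
    for gene in block:
        i = genes.index(gene)
        values[i] = loading * factor + np.sqrt(1 - loading**2) * rng.standard_normal(n_cl)
    if config.dependency_missing_fraction > 0:
        miss = rng.random(values.shape) < config.dependency_missing_fraction
        miss[0] = False  # keep the query profile complete
        values[miss] = np.nan
    frame = pd.DataFrame(
        values, index=genes, columns=[f"ACH{j + 1:03d}" for j in range(n_cl)]
    )
    truth = Truth(
        kind="dependency",
        payload={
            "query": QUERY_ID,
            "correlated_block": block,
            "correlation": config.dependency_correlation,
        },
    )
    return frame, truth


def gen_halflife(config: GeneratorConfig) -> tuple[HalfLifeTable, Truth]:
    """Log-normal enzyme half-lives with the query planted at a known quantile.

    Per cell line the enzyme background is drawn log-normal (hours); the
    query's half-life is placed between the order statistics of the
    quantified background so that its rank percentile among the m + 1
    quantified enzymes (query included) equals ``query_halflife_quantile``
    to within 0.5 / (m + 1), i.e. the planted quantile is recoverable to
    within 1/n by construction.
    """
    rng = config.rng("halflife")
    enzymes = gene_ids(config.n_enzymes, prefix="E")
    q = config.query_halflife_quantile
    columns = {}
    planted_pct = {}
    for cl in config.halflife_cell_lines:
        draws = rng.lognormal(config.halflife_log_mean, config.halflife_log_sd, config.n_enzymes)
        if config.halflife_missing_fraction > 0:
            miss = rng.random(config.n_enzymes) < config.halflife_missing_fraction
            draws[miss] = np.nan
        quantified = np.sort(draws[np.isfinite(draws)])
        m = len(quantified)
        k = int(np.clip(round(q * (m + 1) - 1), 0, m - 1))
        if k == 0:
            query_value = float(quantified[0] * 0.9)
        else:
            query_value = float((quantified[k - 1] + quantified[k]) / 2.0)
        columns[cl] = np.concatenate([[query_value], draws])
        planted_pct[cl] = 100.0 * (k + 1) / (m + 1)
    frame = pd.DataFrame(columns, index=[QUERY_ID] + enzymes)
    table = HalfLifeTable(
        half_life_hours=frame, enzyme_ids=frozenset([QUERY_ID] + enzymes)
    )
    truth = Truth(
        kind="halflife",
        payload={
            "query": QUERY_ID,
            "planted_quantile": config.query_halflife_quantile,
            "planted_percentile": planted_pct,
        },
    )
    return table, truth


def gen_network(config: GeneratorConfig) -> tuple[nx.Graph, Truth]:
    """Erdős–Rényi background network, optionally with a planted clique.

    The clique spans the planted interactor set (whose ids are among the
    node labels), emulating an interactor set that forms known complexes.
    Edge confidences are uniform on (0.4, 1].
    """
    rng = config.rng("network")
    nodes = gene_ids(config.n_network_nodes)
    graph = nx.gnp_random_graph(
        len(nodes), config.edge_probability, seed=int(rng.integers(2**31))
    )
    graph = nx.relabel_nodes(graph, dict(enumerate(nodes)))
    for a, b in graph.edges:
        graph[a][b]["confidence"] = float(0.4 + 0.6 * rng.random())
    clique = gene_ids(config.n_true_interactors)
    if config.planted_clique:
        for i, a in enumerate(clique):
            for b in clique[i + 1 :]:
                if not graph.has_edge(a, b):
                    graph.add_edge(a, b, confidence=0.9)
    truth = Truth(
        kind="network",
        payload={"clique_nodes": clique if config.planted_clique else []},
    )
    return graph, truth


def gen_bundle(config: GeneratorConfig) -> dict[str, Any]:
    """Generate the full coherent synthetic world for end-to-end runs."""
    evidence, annotations, ipms_truth = gen_ipms(config)
    compendium, compendium_truth = gen_compendium(config)
    collection, signature_truth = gen_signatures(config)
    connectivity, connectivity_truth = gen_connectivity_signatures(config)
    dependency, dependency_truth = gen_dependency(config)
    halflife, halflife_truth = gen_halflife(config)
    network, network_truth = gen_network(config)
    return {
        "config": config,
        "ipms": {"evidence": evidence, "annotations": annotations, "truth": ipms_truth},
        "compendium": {"datasets": compendium, "truth": compendium_truth},
        "signatures": {"collection": collection, "truth": signature_truth},
        "connectivity": {"signatures": connectivity, "truth": connectivity_truth},
        "dependency": {"matrix": dependency, "truth": dependency_truth},
        "halflife": {"table": halflife, "truth": halflife_truth},
        "network": {"graph": network, "truth": network_truth},
        "interactor_set": interactor_gene_set(config),
    }
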