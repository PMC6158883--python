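"""End-to-end orchestration: interactors -> co-expression -> enrichment ->
knockdown signatures -> network and screens.

The pipeline runs its stages in dependency order from a single config,
writing one TSV per stage plus a JSON manifest that records the package
version, seed, per-stage parameters and headline numbers.  The interactor
set written by stage 1 is read back from disk before being handed to the
downstream stages, so what they consume is byte-identical to what was
reported.  Inputs come either from files or from the synthetic-data
generators (the default when no paths are given).
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .coexpression import (
    CoexpressionParams,
    build_coexpression_matrix,
    overall_scores,
    rank_datasets,
)
from .datatypes import GeneSet
from .enrichment import percentile_membership, permutation_pvalue
from .interactors import InteractorCallConfig, call_high_confidence, called_set
from .screens import correlate_dependencies, edge_enrichment, halflife_percentile
from .signatures import (
    cluster_connectivity,
    consensus_signature,
    pairwise_connectivity,
    select_hairpins,
    signature_set_enrichment,
    tree_to_newick,
)
from .simulate import GeneratorConfig, QUERY_ID, gen_bundle


@dataclass
class PipelineConfig:
    """One config for the whole run.

    With no input paths, every stage runs on the coherent synthetic bundle
    generated from ``generator`` (whose seed is taken from ``seed``).
    File-backed inputs may replace any subset: evidence + annotations for
    the IP-MS stage, a signature matrix for the knockdown stage, edge
    lists and matrices for the screens.
    """

    out_dir: str = "moonpipe_run"
    seed: int = 0
    query: str = QUERY_ID

    # stage toggles
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "interactors": True,
            "coexpression": True,
            "signatures": True,
            "network": True,
            "dependency": True,
            "halflife": True,
        }
    )

    # thresholds
    call: InteractorCallConfig = field(default_factory=InteractorCallConfig)
    coexpression: CoexpressionParams = field(default_factory=CoexpressionParams)
    n_perm: int = 10_000
    percentile_q: float = 0.95
    k_hairpins: int = 3
    exclude_cell_lines: tuple[str, ...] = ()
    connectivity_top_n: int = 150
    edge_draws: int = 100_000
    alpha: float = 0.05

    # optional file inputs (synthetic bundle fills the gaps)
    evidence_path: str | None = None
    annotations_path: str | None = None
    signature_matrix_path: str | None = None
    network_path: str | None = None
    dependency_path: str | None = None
    halflife_path: str | None = None
    enzymes_path: str | None = None

    generator: GeneratorConfig | None = None


class StageFailed(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; return the manifest (also written to disk).

    A failed stage is recorded with its error and every downstream stage
    that depends on it is skipped with an explicit manifest entry.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    generator = config.generator or GeneratorConfig(seed=config.seed)
    bundle = gen_bundle(generator)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    input_hashes = {}
    for attr in (
        "evidence_path", "annotations_path", "signature_matrix_path",
        "network_path", "dependency_path", "halflife_path", "enzymes_path",
    ):
        path = getattr(config, attr)
        if path and Path(path).exists():
            import hashlib

            input_hashes[attr] = hashlib.sha256(
                Path(path).read_bytes()
            ).hexdigest()[:16]
    manifest["input_hashes"] = input_hashes
    header = io.provenance_header(seed=config.seed)

    def record(stage: str, status: str, **info) -> None:
        manifest["stages"][stage] = {"status": status, **info}

    gene_set: GeneSet | None = None

    # ---- stage 1: interactor calling -------------------------------------
    if config.stages.get("interactors", True):
        try:
            if config.evidence_path and config.annotations_path:
                evidence, annotations = io.read_evidence(
                    config.evidence_path, config.annotations_path
                )
            else:
                ipms = bundle["ipms"]
                from .datatypes import validate_annotations, validate_evidence

                annotations = validate_annotations(ipms["annotations"])
                evidence = validate_evidence(ipms["evidence"], annotations)
            report = call_high_confidence(evidence, annotations, config.call)
            io.write_table(report, out / "interactor_calls.tsv", header=header)
            members = [p for p in called_set(report) if p != config.query]
            gene_set = GeneSet(
                name="called_interactors",
                members=frozenset(members),
                description=f"high-confidence interactors of {config.query}",
            )
            io.write_gmt([gene_set], out / "interactor_set.gmt")
            # re-read so downstream consumes exactly what was written
            gene_set = io.read_gmt(out / "interactor_set.gmt")[0]
            record(
                "interactors",
                "ok",
                n_called=len(gene_set),
                params={
                    "min_unique_peptides": config.call.min_unique_peptides,
                    "min_fraction": config.call.min_fraction_per_bait_antibody,
                },
            )
        except Exception as exc:
            record("interactors", "failed", error=str(exc), trace=traceback.format_exc())
    else:
        record("interactors", "disabled")

    def needs_set(stage: str) -> bool:
        if gene_set is None:
            record(stage, "skipped", reason="interactor set unavailable")
            return False
        return True

    # ---- stage 2: co-expression + enrichment -----------------------------
    if config.stages.get("coexpression", True):
        if needs_set("coexpression"):
            try:
                matrix = build_coexpression_matrix(
                    bundle["compendium"]["datasets"], config.query, config.coexpression
                )
                scores = overall_scores(matrix)
                ranked_ds = rank_datasets(
                    matrix, scores, gene_set, k=config.coexpression.top_k_datasets
                )
                io.write_table(matrix.indicator, out / "coexpression_matrix.tsv", header=header)
                io.write_table(
                    pd.DataFrame({"score": scores.score, "coverage": scores.coverage}),
                    out / "coexpression_scores.tsv",
                    header=header,
                )
                io.write_table(ranked_ds, out / "ranked_datasets.tsv", header=header, index=False)
                universe = scores.score[scores.coverage > 0]
                enr = permutation_pvalue(
                    universe, gene_set, n_perm=config.n_perm, seed=config.seed
                )
                count, size, _, threshold = percentile_membership(
                    scores, gene_set, q=config.percentile_q
                )
                record(
                    "coexpression",
                    "ok",
                    es=enr.es,
                    p_value=enr.p_value,
                    percentile_members=count,
                    set_size=size,
                    percentile_threshold=threshold,
                    top_dataset=str(ranked_ds.iloc[0]["dataset_id"]),
                )
            except Exception as exc:
                record("coexpression", "failed", error=str(exc), trace=traceback.format_exc())
    else:
        record("coexpression", "disabled")

    # ---- stage 3: knockdown signatures -----------------------------------
    if config.stages.get("signatures", True):
        if needs_set("signatures"):
            try:
                if config.signature_matrix_path:
                    collection = io.read_signature_matrix(config.signature_matrix_path)
                else:
                    collection = bundle["signatures"]["collection"]
                exclude = list(config.exclude_cell_lines) or list(
                    bundle["signatures"]["truth"].payload["sparse_cell_lines"]
                )
                hairpins = select_hairpins(collection, config.query, k=config.k_hairpins)
                consensus = consensus_signature(collection, hairpins, exclude)
                enr = signature_set_enrichment(
                    consensus, gene_set, n_perm=config.n_perm, seed=config.seed
                )
                io.write_table(
                    consensus.values.to_frame("z_mean"),
                    out / "consensus_signature.tsv",
                    header=header,
                )
                conn = pairwise_connectivity(
                    bundle["connectivity"]["signatures"], top_n=config.connectivity_top_n
                )
                order, tree = cluster_connectivity(conn)
                io.write_table(conn, out / "connectivity.tsv", header=header)
                (out / "connectivity_tree.nwk").write_text(
                    tree_to_newick(tree, list(conn.index)) + "\n"
                )
                record(
                    "signatures",
                    "ok",
                    hairpins=hairpins,
                    excluded_cell_lines=exclude,
                    n_contributors=len(consensus.contributors),
                    es=enr.es,
                    p_value=enr.p_value,
                    leaf_order=order,
                )
            except Exception as exc:
                record("signatures", "failed", error=str(exc), trace=traceback.format_exc())
    else:
        record("signatures", "disabled")

    # ---- stage 4: network edge enrichment --------------------------------
    if config.stages.get("network", True):
        if needs_set("network"):
            try:
                network = (
                    io.read_network(config.network_path)
                    if config.network_path
                    else bundle["network"]["graph"]
                )
                result = edge_enrichment(
                    network, set(gene_set.members), n_draws=config.edge_draws,
                    seed=config.seed,
                )
                record(
                    "network",
                    "ok",
                    observed_edges=result.observed_edges,
                    expected_edges=result.expected_edges,
                    fold=result.fold,
                    p_value=result.p_value,
                )
            except Exception as exc:
                record("network", "failed", error=str(exc), trace=traceback.format_exc())
    else:
        record("network", "disabled")

    # ---- stage 5: dependency screen --------------------------------------
    if config.stages.get("dependency", True):
        try:
            dep = (
                io.read_matrix(config.dependency_path)
                if config.dependency_path
                else bundle["dependency"]["matrix"]
            )
            table = correlate_dependencies(dep, config.query, alpha=config.alpha)
            io.write_table(table, out / "dependency_screen.tsv", header=header)
            record(
                "dependency",
                "ok",
                n_significant=int(table["significant"].sum()),
                n_tested=table.attrs["n_tested"],
            )
        except Exception as exc:
            record("dependency", "failed", error=str(exc), trace=traceback.format_exc())
    else:
        record("dependency", "disabled")

    # ---- stage 6: half-life percentiles ----------------------------------
    if config.stages.get("halflife", True):
        try:
            if config.halflife_path and config.enzymes_path:
                hl = io.read_halflife(config.halflife_path, config.enzymes_path)
            else:
                hl = bundle["halflife"]["table"]
            pct, _curves = halflife_percentile(hl, config.query)
            io.write_table(pct, out / "halflife_percentiles.tsv", header=header, index=False)
            record(
                "halflife",
                "ok",
                percentiles={
                    str(row["cell_line"]): float(row["percentile"])
                    for _, row in pct.iterrows()
                },
            )
        except Exception as exc:
            record("halflife", "failed", error=str(exc), trace=traceback.format_exc())
    else:
        record("halflife", "disabled")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
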