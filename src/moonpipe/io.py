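"""Readers and writers for the plain-text formats the pipeline touches.

GMT for gene sets; TSV for peptide evidence, sample annotations,
dependency and half-life matrices and network edge lists; a dense GCT-like
TSV dialect for perturbation signature matrices.  Output tables may carry
a commented provenance header (lines starting with ``#``) recording the
tool version, seed and input hashes; all readers skip such lines.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from . import __version__
from .datatypes import (
    GeneSet,
    HalfLifeTable,
    SignatureCollection,
    build_network,
    validate_annotations,
    validate_evidence,
)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


# ---------------------------------------------------------------------------
# provenance headers

def provenance_header(seed: int | None = None, inputs: Sequence[str | Path] = ()) -> str:
    """Commented header recording version, seed and input-file hashes."""
    lines = [f"# moonpipe {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for path in inputs:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        lines.append(f"# input: {Path(path).name} sha256:{digest}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: str | Path, header: str = "", index: bool = True) -> None:
    """Write a TSV table, optionally preceded by a commented header."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a TSV table written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file.

    Each non-empty line is ``name<TAB>description<TAB>member...`` with at
    least one member; duplicate member ids within a line are collapsed.
    Set order is preserved.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, members=frozenset(members), description=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# IP-MS evidence

def read_annotations(path: str | Path) -> pd.DataFrame:
    return validate_annotations(pd.read_csv(path, sep="\t", comment="#"))


def read_evidence(
    evidence_path: str | Path, annotation_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate a peptide-evidence table and its annotations.

    Returns ``(evidence, annotations)``; zero-count evidence rows are
    dropped and both tables' invariants are enforced (see
    :mod:`moonpipe.datatypes`).
    """
    annotations = read_annotations(annotation_path)
    evidence = validate_evidence(
        pd.read_csv(evidence_path, sep="\t", comment="#"), annotations
    )
    return evidence, annotations


def write_evidence(
    evidence: pd.DataFrame, annotations: pd.DataFrame,
    evidence_path: str | Path, annotation_path: str | Path,
) -> None:
    ev = evidence.copy()
    ann = annotations.copy()
    for col in ("genotype", "antibody"):
        ann[col] = ann[col].map(lambda v: getattr(v, "value", v))
    ev.to_csv(evidence_path, sep="\t", index=False)
    ann.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signature matrices (dense GCT-like TSV)

_ANNOTATION_ROWS = list(SignatureCollection.REQUIRED_ANNOTATIONS)


def read_signature_matrix(path: str | Path) -> SignatureCollection:
    """Read a dense GCT-like signature matrix.

    Layout: a single header line of experiment ids (first cell ``id``),
    followed by three annotation rows named ``perturbed_gene``,
    ``hairpin_id`` and ``cell_line``, followed by one numeric row per gene.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    missing = [r for r in _ANNOTATION_ROWS if r not in df.index]
    if missing:
        raise ParseError(f"{path}: missing annotation rows: {missing}")
    annotations = df.loc[_ANNOTATION_ROWS].T
    annotations.index.name = None
    annotations.columns.name = None
    body = df.drop(index=_ANNOTATION_ROWS)
    coerced = body.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & body.notna()
    if bad.any().any() or body.isna().any().any():
        mask = bad | body.isna()
        gene = mask.any(axis=1).idxmax()
        col = mask.loc[gene].idxmax()
        raise ParseError(
            f"{path}: non-numeric or missing value at gene {gene!r}, "
            f"experiment {col!r}"
        )
    numeric = body.astype(float)  # exact parse; to_numeric's parser is lossy
    numeric.index.name = None
    numeric.columns.name = None
    return SignatureCollection(z=numeric, annotations=annotations)


def write_signature_matrix(collection: SignatureCollection, path: str | Path) -> None:
    """Write a signature matrix in the dialect read by :func:`read_signature_matrix`.

    Values are written with 17 significant digits so a write/read
    round-trip reproduces the floats exactly.
    """
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, collection.z.columns)) + "\n")
        for row in _ANNOTATION_ROWS:
            fh.write(row + "\t" + "\t".join(collection.annotations[row].astype(str)) + "\n")
        for gene, values in collection.z.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(f"{v:.17g}" for v in values) + "\n")


# ---------------------------------------------------------------------------
# matrices, lists, networks

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a numeric matrix TSV (rows x columns, first column = row id)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_id_list(path: str | Path) -> list[str]:
    """Read one identifier per line, ignoring blanks and ``#`` comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.append(token)
    return out


def read_halflife(table_path: str | Path, enzymes_path: str | Path) -> HalfLifeTable:
    return HalfLifeTable(
        half_life_hours=read_matrix(table_path),
        enzyme_ids=frozenset(read_id_list(enzymes_path)),
    )


def read_network(path: str | Path, min_confidence: float = 0.4) -> nx.Graph:
    """Read an undirected scored edge list (``protein_a  protein_b  confidence``)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["protein_a", "protein_b", "confidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: edge list missing columns {missing}")
    return build_network(
        df[required].itertuples(index=False, name=None), min_confidence=min_confidence
    )


def write_network(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {"protein_a": a, "protein_b": b, "confidence": d.get("confidence", 1.0)}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"]).to_csv(
        path, sep="\t", index=False
    )
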