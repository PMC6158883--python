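"""Core containers shared by all pipeline stages.

The pipeline traffics in a handful of tabular objects: unique-peptide
evidence from immunoprecipitation/mass-spectrometry (IP-MS) experiments,
expression compendia, gene sets, perturbation z-score signatures,
dependency-screen matrices, protein half-life tables and a background
protein-protein interaction network.  Everything tabular is held in pandas
objects; the thin dataclasses below exist to bundle a matrix with the
annotations it cannot be interpreted without, and to give validation a
single home.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


class Genotype(str, enum.Enum):
    """Cell genotype of an IP-MS lysate: parental or bait-knockout."""

    WT = "WT"
    KO = "KO"


class Antibody(str, enum.Enum):
    """Antibody used for the pull-down.

    Two independent antibodies against the bait plus an isotype (IgG)
    control; proteins recovered by the isotype antibody are non-specific
    binders.
    """

    BAIT_1 = "bait-1"
    BAIT_2 = "bait-2"
    ISOTYPE = "isotype"


BAIT_ANTIBODIES = (Antibody.BAIT_1, Antibody.BAIT_2)

#: (genotype, antibody) groups in which a high-confidence interactor must
#: be entirely undetected: every knockout pull-down and the isotype control.
DEFAULT_FORBIDDEN_GROUPS = frozenset(
    {
        (Genotype.KO, Antibody.BAIT_1),
        (Genotype.KO, Antibody.BAIT_2),
        (Genotype.KO, Antibody.ISOTYPE),
        (Genotype.WT, Antibody.ISOTYPE),
    }
)

ANNOTATION_COLUMNS = ["sample_id", "genotype", "antibody", "replicate"]
EVIDENCE_COLUMNS = ["protein_id", "sample_id", "unique_peptides"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Validate an IP-MS sample annotation table.

    Requires columns ``sample_id, genotype, antibody, replicate``; sample
    ids must be unique, genotype/antibody must be recognised labels, and
    replicate indices within each (genotype, antibody) group must be
    1..n with no gaps.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns: {missing}")
    ann = annotations.loc[:, ANNOTATION_COLUMNS].copy()
    dup = ann["sample_id"][ann["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample ids: {sorted(set(dup))}")
    try:
        ann["genotype"] = ann["genotype"].map(Genotype)
        ann["antibody"] = ann["antibody"].map(Antibody)
    except ValueError as exc:
        raise ValidationError(f"unrecognised genotype/antibody label: {exc}") from exc
    ann["replicate"] = ann["replicate"].astype(int)
    if (ann["replicate"] < 1).any():
        raise ValidationError("replicate indices must be positive")
    for (gt, ab), grp in ann.groupby(["genotype", "antibody"], observed=True):
        reps = sorted(grp["replicate"])
        if reps != list(range(1, len(reps) + 1)):
            raise ValidationError(
                f"replicates of group ({gt.value}, {ab.value}) are {reps}, "
                f"expected 1..{len(reps)} with no gaps"
            )
    return ann.reset_index(drop=True)


def validate_evidence(
    evidence: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Validate a peptide-evidence table against its sample annotations.

    Enforces one record per (protein, sample), non-negative counts and
    sample ids drawn from the annotation table; rows with a zero count are
    dropped (absence of a record means zero detection).
    """
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise ValidationError(f"evidence table missing columns: {missing}")
    ev = evidence.loc[:, EVIDENCE_COLUMNS].copy()
    ev["unique_peptides"] = ev["unique_peptides"].astype(int)
    if (ev["unique_peptides"] < 0).any():
        bad = ev.loc[ev["unique_peptides"] < 0, "protein_id"].tolist()
        raise ValidationError(f"negative unique-peptide counts for: {bad}")
    dup = ev.duplicated(subset=["protein_id", "sample_id"])
    if dup.any():
        pairs = ev.loc[dup, ["protein_id", "sample_id"]].itertuples(index=False)
        raise ValidationError(
            "duplicate (protein, sample) records: " + ", ".join(map(str, pairs))
        )
    known = set(annotations["sample_id"])
    unknown = sorted(set(ev["sample_id"]) - known)
    if unknown:
        raise ValidationError(f"evidence references unannotated samples: {unknown}")
    return ev[ev["unique_peptides"] > 0].reset_index(drop=True)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers.

    Identifiers are opaque, case-sensitive strings; duplicates are
    collapsed on construction.
    """

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ExpressionDataset:
    """One expression matrix (features x samples) with a feature-to-gene map.

    ``values`` is indexed by feature id; ``feature_to_gene`` maps each
    feature to a gene id (many-to-one, e.g. multiple microarray probes per
    gene).  Missing measurements are NaN.
    """

    dataset_id: str
    values: pd.DataFrame
    feature_to_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValidationError(
                f"dataset {self.dataset_id!r} has < 2 samples"
            )
        if self.values.index.duplicated().any():
            raise ValidationError(
                f"dataset {self.dataset_id!r} has duplicate feature ids"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CoexpressionMatrix:
    """Binary co-expression indicators, genes x datasets.

    ``indicator`` entries are 1.0 where the gene is co-expressed with the
    query in that dataset, 0.0 where it is measured but not co-expressed,
    and NaN where the gene (or the query) was not adequately measured —
    missingness is distinct from absence of co-expression and is tracked
    as per-gene coverage downstream.
    """

    indicator: pd.DataFrame
    query_gene: str

    def __post_init__(self) -> None:
        if self.query_gene in self.indicator.index:
            row = self.indicator.loc[self.query_gene]
            if not ((row == 1) | row.isna()).all():
                raise ValidationError(
                    "query gene's own indicator must be 1 wherever defined"
                )


@dataclass
class OverallScores:
    """Per-gene overall co-expression score and dataset coverage.

    ``score`` is the sum of the binary indicators over datasets (missing
    entries contribute nothing); ``coverage`` counts the datasets in which
    the gene was measured, so poorly covered genes can be excluded from
    ranked universes.
    """

    score: pd.Series
    coverage: pd.Series


@dataclass
class SignatureCollection:
    """Perturbation z-score signatures (genes x experiments) with annotations.

    ``annotations`` is indexed by experiment id with columns
    ``perturbed_gene``, ``hairpin_id`` and ``cell_line``, mirroring
    Level-5-style knockdown signature data.
    """

    z: pd.DataFrame
    annotations: pd.DataFrame

    REQUIRED_ANNOTATIONS = ("perturbed_gene", "hairpin_id", "cell_line")

    def __post_init__(self) -> None:
        for col in self.REQUIRED_ANNOTATIONS:
            if col not in self.annotations.columns:
                raise ValidationError(f"signature annotations lack {col!r}")
        if list(self.z.columns) != list(self.annotations.index):
            raise ValidationError(
                "signature matrix columns and annotation index disagree"
            )
        import numpy as np

        if not np.isfinite(self.z.to_numpy()).all():
            raise ValidationError("signature z-scores must be finite")

    @property
    def n_experiments(self) -> int:
        return self.z.shape[1]


@dataclass
class ConsensusSignature:
    """Mean z-score vector over a set of contributing experiments."""

    values: pd.Series
    contributors: list[tuple[str, str]] = field(default_factory=list)
    excluded_cell_lines: list[str] = field(default_factory=list)


@dataclass
class HalfLifeTable:
    """Protein half-lives (hours), proteins x cell lines, with an enzyme list.

    ``enzyme_ids`` defines the metabolic-enzyme background against which
    percentiles are computed; only enzymes actually quantified in a given
    cell line enter that cell line's background.
    """

    half_life_hours: pd.DataFrame
    enzyme_ids: frozenset[str]

    def __post_init__(self) -> None:
        if ((self.half_life_hours <= 0).any()).any():
            raise ValidationError("half-lives must be positive")
        if not self.enzyme_ids:
            raise ValidationError("enzyme background is empty")


def build_network(
    edges: Iterable[tuple[str, str, float]], min_confidence: float = 0.4
) -> nx.Graph:
    """Build an undirected interaction network from scored edges.

    Self-loops are rejected; duplicate edges (either orientation) keep the
    highest confidence; edges at or below ``min_confidence`` are dropped
    (the conventional "medium confidence" cut-off for STRING-style scores
    is 0.400, exclusive).
    """
    g = nx.Graph()
    for a, b, conf in edges:
        if a == b:
            raise ValidationError(f"self-loop on node {a!r}")
        if not 0.0 <= conf <= 1.0:
            raise ValidationError(f"confidence {conf} outside [0, 1] for ({a}, {b})")
        if conf <= min_confidence:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)
    return g
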