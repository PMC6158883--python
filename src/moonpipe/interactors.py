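"""High-confidence interactor calling from controlled IP-MS evidence.

The design behind the rule: pull-downs are run with two independent
antibodies against the bait in wild-type cells, and the same antibodies in
bait-knockout cells plus an isotype (IgG) control.  A protein is a
high-confidence interactor when it is reproducibly detected with *both*
bait antibodies in wild-type lysates — at least ``min_unique_peptides``
unique peptides in at least ``min_fraction_per_bait_antibody`` of that
antibody's wild-type samples — and is never detected (any peptide count)
in any knockout or isotype-control sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .datatypes import (
    BAIT_ANTIBODIES,
    DEFAULT_FORBIDDEN_GROUPS,
    Antibody,
    Genotype,
    ValidationError,
)


@dataclass(frozen=True)
class InteractorCallConfig:
    """Parameters of the high-confidence calling rule.

    The defaults encode the two-antibody / knockout / isotype criterion:
    >= 2 unique peptides in >= 50% of wild-type samples per bait antibody,
    and zero detection in every knockout and isotype sample.
    ``detection_threshold_in_controls`` is the peptide count at which a
    control-sample record disqualifies; the default 1 means *any* record
    disqualifies, which is stricter than the wild-type threshold.
    """

    min_unique_peptides: int = 2
    min_fraction_per_bait_antibody: float = 0.5
    forbid_detection_in: frozenset[tuple[Genotype, Antibody]] = field(
        default_factory=lambda: DEFAULT_FORBIDDEN_GROUPS
    )
    detection_threshold_in_controls: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction_per_bait_antibody <= 1:
            raise ValidationError(
                "min_fraction_per_bait_antibody must be in (0, 1]"
            )
        if self.min_unique_peptides < 1:
            raise ValidationError("min_unique_peptides must be positive")


def _group_key(genotype: Genotype, antibody: Antibody) -> str:
    return f"{genotype.value}/{antibody.value}"


def call_high_confidence(
    evidence: pd.DataFrame,
    annotations: pd.DataFrame,
    config: InteractorCallConfig | None = None,
) -> pd.DataFrame:
    """Apply the high-confidence interactor rule to every observed protein.

    Parameters
    ----------
    evidence, annotations
        Validated tables as returned by :func:`moonpipe.io.read_evidence`.
    config
        Calling thresholds; defaults reproduce the standard criterion.

    Returns
    -------
    DataFrame indexed by protein id with, per (genotype, antibody) group,
    ``detected_<group>`` / ``n_<group>`` counts and a ``frac_<group>``
    string such as ``"3/4"``, plus a boolean ``called`` column and a
    semicolon-joined ``reasons`` column for proteins that fail.  Sorted by
    descending total wild-type peptide count, then protein id.
    """
    config = config or InteractorCallConfig()
    ann = annotations.copy()
    groups = {
        (gt, ab): list(grp["sample_id"])
        for (gt, ab), grp in ann.groupby(["genotype", "antibody"], observed=True)
    }
    bait_groups = {
        ab: groups.get((Genotype.WT, ab), []) for ab in BAIT_ANTIBODIES
    }
    for ab, samples in bait_groups.items():
        if not samples:
            raise ValidationError(
                f"no wild-type samples for bait antibody {ab.value!r}"
            )
    forbidden_samples: dict[tuple[Genotype, Antibody], list[str]] = {}
    for key in sorted(config.forbid_detection_in, key=lambda k: (k[0].value, k[1].value)):
        samples = groups.get(key, [])
        if not samples:
            warnings.warn(
                f"forbidden group {_group_key(*key)} has no samples; "
                "its criterion passes vacuously",
                stacklevel=2,
            )
        forbidden_samples[key] = samples

    if len(evidence) == 0:
        return pd.DataFrame(
            columns=["called", "reasons", "total_wt_peptides"]
        ).rename_axis("protein_id")

    counts = (
        evidence.pivot(index="protein_id", columns="sample_id", values="unique_peptides")
        .reindex(columns=ann["sample_id"], fill_value=0)
        .fillna(0)
        .astype(int)
    )

    report = pd.DataFrame(index=counts.index)
    pass_bait = pd.Series(True, index=counts.index)
    reasons = pd.Series([[] for _ in counts.index], index=counts.index)

    for ab, samples in bait_groups.items():
        key = _group_key(Genotype.WT, ab)
        detected = (counts[samples] >= config.min_unique_peptides).sum(axis=1)
        frac_ok = detected / len(samples) >= config.min_fraction_per_bait_antibody
        report[f"detected_{key}"] = detected
        report[f"n_{key}"] = len(samples)
        report[f"frac_{key}"] = detected.map(lambda d, n=len(samples): f"{d}/{n}")
        pass_bait &= frac_ok
        for pid in counts.index[~frac_ok]:
            reasons[pid].append(
                f"detected in {detected[pid]}/{len(samples)} {key} samples "
                f"(need >= {config.min_fraction_per_bait_antibody:g})"
            )

    pass_controls = pd.Series(True, index=counts.index)
    for (gt, ab), samples in forbidden_samples.items():
        key = _group_key(gt, ab)
        if samples:
            hit = (counts[samples] >= config.detection_threshold_in_controls).any(axis=1)
        else:
            hit = pd.Series(False, index=counts.index)
        det = (counts[samples] >= config.detection_threshold_in_controls).sum(axis=1) if samples else 0
        report[f"detected_{key}"] = det
        report[f"n_{key}"] = len(samples)
        pass_controls &= ~hit
        for pid in counts.index[hit]:
            reasons[pid].append(f"detected in forbidden group {key}")

    wt_samples = [s for samples in bait_groups.values() for s in samples]
    report["total_wt_peptides"] = counts[wt_samples].sum(axis=1)
    report["called"] = pass_bait & pass_controls
    report["reasons"] = reasons.map("; ".join)
    order = sorted(
        report.index, key=lambda pid: (-report.at[pid, "total_wt_peptides"], pid)
    )
    return report.loc[order].rename_axis("protein_id")


def called_set(report: pd.DataFrame) -> list[str]:
    """Protein ids called high-confidence, in report order."""
    if "called" not in report.columns:
        return []
    return list(report.index[report["called"].astype(bool)])


def bait_recovery(
    evidence: pd.DataFrame, annotations: pd.DataFrame, bait_id: str
) -> pd.DataFrame:
    """Unique-peptide counts for the bait protein in every sample.

    Returns one row per sample (genotype, antibody, replicate,
    unique_peptides), with explicit zeros for samples lacking a bait
    record; warns if the bait was not detected anywhere.
    """
    ann = annotations.copy()
    bait = evidence[evidence["protein_id"] == bait_id]
    if len(bait) == 0:
        warnings.warn(f"bait {bait_id!r} absent from all samples", stacklevel=2)
    table = ann.merge(
        bait[["sample_id", "unique_peptides"]], on="sample_id", how="left"
    )
    table["unique_peptides"] = table["unique_peptides"].fillna(0).astype(int)
    table["genotype"] = table["genotype"].map(lambda v: getattr(v, "value", v))
    table["antibody"] = table["antibody"].map(lambda v: getattr(v, "value", v))
    return table.sort_values(["genotype", "antibody", "replicate"]).reset_index(
        drop=True
    )
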