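"""Curated reference: the MTHFD2 high-confidence interactor table.

Published co-immunoprecipitation experiments in HCT-116 cells (12 IP-MS
samples: wild-type 4 + 2 bait-antibody and 2 isotype; knockout 2 + 2)
identified 29 high-confidence MTHFD2 interactors with, for each protein,
the fraction of wild-type samples per bait antibody in which at least two
unique peptides were detected.  Those per-antibody detection fractions
are curated here, together with the MTHFD1 counter-example (detected with
one bait antibody but also in knockout samples, hence rejected).

:func:`reference_evidence` expands the fractions into a *synthetic*
peptide-evidence table — a stand-in reconstruction, not the original
supplementary data: which specific replicates carried the detections, and
the exact peptide counts, are not recorded in the fractions, so arbitrary
deterministic choices are made (the first replicates of each group detect,
with exactly two unique peptides).  The calling rule is invariant to both
choices, so running the default filter over this table must recover
exactly the 29 curated interactors and their fractions.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import GeneSet

BAIT = "MTHFD2"

#: protein -> (detections with bait antibody 1 of 4 WT samples,
#:             detections with bait antibody 2 of 2 WT samples)
INTERACTOR_DETECTIONS: dict[str, tuple[int, int]] = {
    "HSPA8": (3, 1),
    "HSPA9": (3, 1),
    "HSPB1": (3, 1),
    "HSPD1": (3, 1),
    "NPM1": (2, 1),
    "HIST1H3A": (2, 1),
    "HIST2H3A": (2, 1),
    "HIST3H3": (2, 1),
    "H3F3A": (2, 1),
    "XRCC6": (2, 1),
    "RPA1": (2, 1),
    "HNRNPK": (2, 1),
    "HNRNPM": (3, 1),
    "SYNCRIP": (2, 1),
    "HNRNPR": (2, 1),
    "HNRNPU": (2, 2),
    "SF3B3": (2, 1),
    "LRPPRC": (3, 1),
    "ILF2": (2, 1),
    "NUFIP2": (2, 1),
    "DDX3X": (2, 1),
    "RPL18": (2, 1),
    "RPS13": (2, 1),
    "RPS3A": (2, 1),
    "RPS5": (2, 1),
    "RPS8": (2, 1),
    "ENO1": (2, 1),
    "EZR": (2, 1),
    "RPN1": (2, 1),
}


def interactor_set() -> GeneSet:
    """The 29-member high-confidence MTHFD2 interactor gene set."""
    return GeneSet(
        name="D2PPI",
        members=frozenset(INTERACTOR_DETECTIONS),
        description="high-confidence MTHFD2 physical interactors (HCT-116 IP-MS)",
    )


def reference_annotations() -> pd.DataFrame:
    """The 12-sample IP-MS design of the reference experiment."""
    rows = []
    for genotype, antibody, n in (
        ("WT", "bait-1", 4),
        ("WT", "bait-2", 2),
        ("WT", "isotype", 2),
        ("KO", "bait-1", 2),
        ("KO", "bait-2", 2),
    ):
        for rep in range(1, n + 1):
            rows.append(
                {
                    "sample_id": f"{genotype}_{antibody}_r{rep}",
                    "genotype": genotype,
                    "antibody": antibody,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def reference_evidence(peptides_per_detection: int = 2) -> pd.DataFrame:
    """Synthetic evidence table consistent with the curated fractions.

    Each interactor is given ``peptides_per_detection`` unique peptides in
    the first ``a`` of the four bait-1 wild-type samples and the first
    ``b`` of the two bait-2 wild-type samples, and nothing anywhere else.
    MTHFD1 is added as the known rejected case: detected with bait
    antibody 1 in wild-type samples but also in a knockout sample.  The
    bait itself is detected in every wild-type bait sample.
    """
    records = []
    for rep in range(1, 5):
        records.append((BAIT, f"WT_bait-1_r{rep}", 10))
    for rep in range(1, 3):
        records.append((BAIT, f"WT_bait-2_r{rep}", 8))
    for protein, (ab1, ab2) in INTERACTOR_DETECTIONS.items():
        for rep in range(1, ab1 + 1):
            records.append((protein, f"WT_bait-1_r{rep}", peptides_per_detection))
        for rep in range(1, ab2 + 1):
            records.append((protein, f"WT_bait-2_r{rep}", peptides_per_detection))
    # rejected case: wild-type bait-1 detections but knockout detection too
    for rep in range(1, 3):
        records.append(("MTHFD1", f"WT_bait-1_r{rep}", peptides_per_detection))
    records.append(("MTHFD1", "KO_bait-1_r1", peptides_per_detection))
    return pd.DataFrame(records, columns=["protein_id", "sample_id", "unique_peptides"])
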