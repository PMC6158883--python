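"""Shared fixtures: small validated IP-MS tables and a default generator config."""

from __future__ import annotations

import pandas as pd
import pytest

from moonpipe.datatypes import validate_annotations, validate_evidence
from moonpipe.simulate import GeneratorConfig


@pytest.fixture()
def annotations_12() -> pd.DataFrame:
    """The canonical 12-sample controlled IP-MS design."""
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
    return validate_annotations(pd.DataFrame(rows))


def make_evidence(records, annotations):
    """Build a validated evidence table from (protein, sample, count) tuples."""
    ev = pd.DataFrame(records, columns=["protein_id", "sample_id", "unique_peptides"])
    return validate_evidence(ev, annotations)


@pytest.fixture()
def generator_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7)
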