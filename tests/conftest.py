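"""Shared fixtures: hand-built toy matrices and a moderate planted atlas."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from protatlas.core import AbundanceMatrix, macro_region_of
from protatlas.simulate import SimConfig, simulate_atlas


def build_matrix(lfq_rows: dict[str, list[float]],
                 sample_specs: list[tuple[str, str]],
                 days: dict[str, int] | None = None) -> AbundanceMatrix:
    """Construct an AbundanceMatrix from explicit values.

    ``sample_specs`` is a list of (stage, region); replicate indices and
    sample ids are generated.  ``lfq_rows`` maps protein id to one intensity
    per sample.
    """
    days = days or {"F50": 50, "F90": 90, "F120": 120, "P3": 153}
    counter: dict[tuple[str, str], int] = {}
    rows = []
    for stage, region in sample_specs:
        counter[(stage, region)] = counter.get((stage, region), 0) + 1
        rep = counter[(stage, region)]
        rows.append((f"{stage}_{region}_R{rep}", stage, days[stage], region,
                     macro_region_of(region), f"{stage}_A{rep}", "biological"))
    meta = pd.DataFrame(rows, columns=["sample_id", "stage", "day", "region",
                                       "macro_region", "animal_id", "replicate_kind"]
                        ).set_index("sample_id")
    lfq = pd.DataFrame(lfq_rows, index=meta.index).T
    lfq.index.name = "protein_id"
    return AbundanceMatrix(lfq, meta)


@pytest.fixture(scope="session")
def planted_atlas():
    """Moderate atlas with planted markers and emergent proteins."""
    return simulate_atlas(SimConfig(n_proteins=500, seed=11))


@pytest.fixture(scope="session")
def noiseless_atlas():
    """No measurement noise, no dropout: structure only."""
    cfg = SimConfig(n_proteins=300, noise_sd=0.0, dropout=0.0, seed=5)
    return simulate_atlas(cfg)
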