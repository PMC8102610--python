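import numpy as np
import pandas as pd
import pytest

from conigen.datatypes import EnvironmentTable, GenotypeMatrix, PopulationMap
from conigen.simdata import SimulationConfig, simulate_dataset


def make_matrix(dosage, sample_ids=None, positions=None, scaffold=None):
    """Small GenotypeMatrix from a (samples x loci) nested list; None -> NaN."""
    dosage = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in dosage]
    )
    n, m = dosage.shape
    sample_ids = sample_ids or [f"s{i+1}" for i in range(n)]
    positions = positions if positions is not None else [(j + 1) * 10 for j in range(m)]
    scaffold = scaffold or ["chr1"] * m
    return GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=[f"L{j+1}" for j in range(m)],
        scaffold=np.array(scaffold, dtype=object),
        position=np.array(positions, dtype=np.int64),
        dosage=dosage,
    )


def make_popmap(assignment, coords=None):
    """PopulationMap from {sample: (population, region)}."""
    rows = {}
    for s, (pop, region) in assignment.items():
        lat, lon = (coords or {}).get(s, (np.nan, np.nan))
        rows[s] = {"population": pop, "region": region, "lat": lat, "lon": lon}
    return PopulationMap(pd.DataFrame(rows).T)


@pytest.fixture(scope="session")
def two_lineage_dataset():
    """Default-condition simulation: 2 regions x 2 populations, strong
    between-lineage divergence, ~2% missing (smaller locus count for
    speed)."""
    cfg = SimulationConfig(n_loci=3000, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """No-missing-data simulation used by complete-case analyses."""
    cfg = SimulationConfig(n_loci=2000, missing_rate=0.0, seed=7)
    return simulate_dataset(cfg)
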