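import numpy as np
import pandas as pd
import pytest

from refugeo.datatypes import AFLPMatrix, Raster
from refugeo.simulate import (
    FounderSimConfig,
    OccurrenceSimConfig,
    simulate_occurrence,
    simulate_serial_founder,
)


@pytest.fixture(scope="session")
def founder_run():
    """One deterministic serial-founder simulation at default parameters."""
    return simulate_serial_founder(FounderSimConfig(seed=11))


@pytest.fixture(scope="session")
def occurrence_table():
    return simulate_occurrence(OccurrenceSimConfig(seed=11))


@pytest.fixture()
def toy_pops_df():
    return pd.DataFrame(
        {
            "pop_id": ["A", "B", "C"],
            "lon": [10.0, 11.0, 12.0],
            "lat": [45.0, 46.0, 47.0],
            "present_4x": [1, 0, 1],
            "present_5x": [0, 1, 0],
            "present_7x": [0, 0, 1],
            "present_8x": [0, 0, 0],
            "elevation": [500.0, 800.0, 1100.0],
            "inclination": [10.0, 20.0, 30.0],
            "aspect": [0.0, 90.0, 180.0],
            "land_use": [0, 1, 0],
            "ndvi": [0.4, 0.5, 0.6],
            "bio04": [5000.0, 6000.0, 7000.0],
            "bio12": [1.0, 8.0, 27.0],
            "bio15": [20.0, 30.0, 40.0],
        }
    )


@pytest.fixture()
def toy_pops_csv(tmp_path, toy_pops_df):
    path = tmp_path / "pops.csv"
    toy_pops_df.to_csv(path, index=False)
    return path


def random_aflp(rng, n_pops=4, n_ind=3, n_loci=6) -> AFLPMatrix:
    individuals, pop_of = [], {}
    for p in range(n_pops):
        for i in range(n_ind):
            ind = f"P{p}_i{i}"
            individuals.append(ind)
            pop_of[ind] = f"P{p}"
    bands = rng.integers(0, 2, size=(n_pops * n_ind, n_loci))
    # guarantee every locus occurs at least once
    empty = bands.sum(axis=0) == 0
    bands[0, empty] = 1
    return AFLPMatrix(individuals=individuals, pop_of=pop_of, bands=bands)


@pytest.fixture()
def uniform_raster():
    return Raster(values=np.ones((7, 7)), xll=0.0, yll=0.0, cellsize=1.0)
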