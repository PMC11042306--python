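"""Shared fixtures: small planted datasets reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from colonnade.data_model import Dataset, NT_COLUMNS, RegionBounds
from colonnade.pins import PinParams, assign_to_columns, build_region_pins
from colonnade.synthetic import SyntheticConfig, simulate_dataset

#: Pin parameters scaled to the synthetic problem size (a few hundred
#: synapses per column instead of thousands); the algorithm is unchanged.
SMALL_PIN_PARAMS = dict(n_avg=8, n_pc=50)


@pytest.fixture(scope="session")
def small_sim():
    """Radius-2 lattice, 6 interleaved columnar types, ~3k synapses."""
    cfg = SyntheticConfig(lattice_radius=2, n_types=6, seed=7)
    return (cfg, *simulate_dataset(cfg))


@pytest.fixture(scope="session")
def small_pins(small_sim):
    cfg, ds, truth = small_sim
    params = PinParams.medulla(**SMALL_PIN_PARAMS)
    return build_region_pins(ds, truth.true_column, params)


@pytest.fixture(scope="session")
def small_assign(small_sim, small_pins):
    _, ds, _ = small_sim
    return assign_to_columns(ds, small_pins)


def tiny_dataset(synapse_rows, neuron_rows, connection_rows, regions=("ME",),
                 depth=30000.0) -> Dataset:
    """Assemble a hand-written Dataset from minimal row dicts."""
    syn_cols = ["synapse_id", "neuron_id", "kind", "x", "y", "z",
                "region", "partner_synapse_id", *NT_COLUMNS]
    syn = pd.DataFrame(synapse_rows, columns=syn_cols)
    for c in ["x", "y", "z", *NT_COLUMNS]:
        syn[c] = pd.to_numeric(syn[c], errors="coerce")
    for c in ["synapse_id", "neuron_id", "kind", "region", "partner_synapse_id"]:
        syn[c] = syn[c].fillna("").astype(str)
    neu = pd.DataFrame(neuron_rows, columns=["neuron_id", "type", "instance", "group", "status"])
    neu = neu.fillna("").astype(str)
    con = pd.DataFrame(connection_rows, columns=["pre", "post", "weight", "region"])
    if len(con):
        con["weight"] = con["weight"].astype(int)
        for c in ["pre", "post", "region"]:
            con[c] = con[c].fillna("").astype(str)
    return Dataset(synapses=syn, neurons=neu, connections=con, regions=list(regions),
                   region_bounds={r: RegionBounds.from_z(0.0, depth) for r in regions})


def probs_for(dominant_col: str, p: float = 0.8) -> dict:
    rest = (1.0 - p) / (len(NT_COLUMNS) - 1)
    return {c: (p if c == dominant_col else rest) for c in NT_COLUMNS}
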