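"""Shared fixtures: tiny synthetic datasets built programmatically."""

import numpy as np
import pytest

from lpindex import Dataset, PopulationRecord, WeightScheme

WINDOW = (1970, 1980)


def make_record(pid, binomial, series, group="Birds", system="terrestrial",
                realm="Palearctic", zone="temperate"):
    return PopulationRecord(
        population_id=pid,
        binomial=binomial,
        group=group,
        system=system,
        realm=realm,
        zone=zone,
        series=series,
        units="individuals",
        source_id="test",
    )


def exponential_series(rate, window=WINDOW, n0=100.0):
    """Noiseless N_t = n0 * rate^(t - base) over the full window."""
    base, final = window
    return {y: n0 * rate ** (y - base) for y in range(base, final + 1)}


@pytest.fixture
def window():
    return WINDOW


@pytest.fixture
def small_dataset():
    """Three species in two taxa of one terrestrial realm, noiseless trends."""
    records = [
        make_record("p1", "Parus major", exponential_series(1.02)),
        make_record("p2", "Parus major", exponential_series(1.01)),
        make_record("p3", "Turdus merula", exponential_series(1.00)),
        make_record("p4", "Salmo trutta", exponential_series(0.95), group="Fish",
                    system="freshwater"),
    ]
    return Dataset(records, WINDOW)


@pytest.fixture
def equal_weights(small_dataset):
    return WeightScheme.equal(small_dataset.group_keys())
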