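import numpy as np
import pytest
import xarray as xr

from reefconnect.deltamaps import Domain, FunctionalNetwork, NetworkLink
from reefconnect.synthetic import (
    PlantedCouplingSpec,
    PlantedDomainSpec,
    SyntheticScenario,
    block_cells,
    generate_ssta,
)


def make_field(values: np.ndarray, lat=None, lon=None, name="ssta") -> xr.DataArray:
    """Wrap a (time, lat, lon) array as an anomaly field."""
    import pandas as pd

    T, nlat, nlon = values.shape
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={
            "time": pd.date_range("1993-04-01", periods=T, freq="MS"),
            "lat": np.linspace(-10, 10, nlat) if lat is None else np.asarray(lat, float),
            "lon": np.linspace(120, 130, nlon) if lon is None else np.asarray(lon, float),
        },
        name=name,
    )


def two_block_scenario(seed=0, noise_sd=0.0, loading=1.0, couplings=(), ar1=0.2, T=288):
    return SyntheticScenario(
        grid_shape=(20, 20),
        n_months=T,
        domains=[
            PlantedDomainSpec("A", block_cells(2, 8, 2, 8), ar1, loading, noise_sd),
            PlantedDomainSpec("B", block_cells(12, 18, 12, 18), ar1, loading, noise_sd),
        ],
        couplings=list(couplings),
        seed=seed,
    )


@pytest.fixture
def noise_free_field():
    field, truth = generate_ssta(two_block_scenario(seed=3))
    return field, truth


def toy_network():
    """Four domains, mixed directions and signs, for hand-enumerated checks.

    Links: D1-D2 undirected +2.0; D3->D1 +1.5; D1->D4 +0.5; D2-D3 undirected
    -1.0; D4->D2 +0.25.
    """
    domains = [
        Domain("D1", frozenset({(0, 0), (0, 1)})),
        Domain("D2", frozenset({(1, 0), (1, 1)})),
        Domain("D3", frozenset({(2, 0), (2, 1)})),
        Domain("D4", frozenset({(3, 0), (3, 1)})),
    ]
    links = [
        NetworkLink("D1", "D2", 2.0, 0, 0.8, "undirected", (0,)),
        NetworkLink("D1", "D3", 1.5, -1, 0.6, "b_to_a", (-1,)),
        NetworkLink("D1", "D4", 0.5, 2, 0.5, "a_to_b", (1, 2)),
        NetworkLink("D2", "D3", -1.0, 0, -0.4, "undirected", (-1, 0)),
        NetworkLink("D4", "D2", 0.25, 1, 0.45, "a_to_b", (1,)),
    ]
    net = FunctionalNetwork(domains=domains, links=links)
    s = net.strengths()
    for d in domains:
        d.strength = s[d.id]
    return net


@pytest.fixture
def mixed_toy_network():
    return toy_network()
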