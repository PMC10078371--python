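import numpy as np
import pytest

from pollinet.networks import BipartiteNetwork
from pollinet.records import harmonize, visits_to_interactions
from pollinet.synth import generate, scenario


def make_net(weights, period="test", provenance="visitation") -> BipartiteNetwork:
    w = np.asarray(weights, dtype=float)
    return BipartiteNetwork(
        plants=[f"p{k}" for k in range(w.shape[0])],
        insects=[f"i{k}" for k in range(w.shape[1])],
        weights=w,
        period=period,
        provenance=provenance,
    )


def random_pruned_matrix(rng, n_rows, n_cols, p=0.5, weighted=False):
    """Random incidence matrix with no empty rows or columns."""
    while True:
        m = (rng.random((n_rows, n_cols)) < p).astype(float)
        if weighted:
            m *= rng.integers(1, 9, size=m.shape)
        if (m.sum(axis=1) > 0).all() and (m.sum(axis=0) > 0).all():
            return m


@pytest.fixture(scope="session")
def baseline_data():
    """One baseline synthetic study (fixed seed) shared across tests."""
    visits, pollen, svd, truth = generate(scenario("baseline", seed=20210))
    return {"visits": visits, "pollen": pollen, "svd": svd, "truth": truth}


@pytest.fixture(scope="session")
def baseline_interactions(baseline_data):
    inter = visits_to_interactions(baseline_data["visits"])
    return harmonize(inter, baseline_data["truth"].taxonomy)
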