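import warnings

import pytest

import hepregen as hg
from hepregen import scoring as sc


@pytest.fixture(scope="session")
def state_data():
    """State-group expression with planted signatures (seed 11)."""
    adata, truth = hg.simulate_state_groups(hg.SimConfig(seed=11))
    return adata, truth


@pytest.fixture(scope="session")
def norm_state(state_data):
    adata, truth = state_data
    return sc.normalize_expression(adata), truth


@pytest.fixture(scope="session")
def reference():
    """Zonated reference at the default study conditions (seed 7)."""
    return hg.simulate_zonated_reference(hg.SimConfig(seed=7))


@pytest.fixture(scope="session")
def reference_norm(reference):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = sc.normalize_expression(reference.expression)
    return hg.LayeredReference(
        expression=norm,
        marker_truth=reference.marker_truth,
        candidate_markers=reference.candidate_markers,
    )


@pytest.fixture(scope="session")
def coip_tables():
    return hg.simulate_coip_tables(hg.SimConfig(seed=5))
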