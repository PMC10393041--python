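import numpy as np
import pytest

from heterbgp.alignment import align_cohort
from heterbgp.model import HETERConfig, HETERParams
from heterbgp.srgraph import build_srgraph, srgraph_from_series, topk_adjacency, distance_matrix
from heterbgp.synthetic import CGMRecord, CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(
        n_t1dm=3,
        n_t2dm=7,
        length_range=(150, 260),
        seed=11,
        volatility_t1dm=2.0,
        volatility_t2dm=5.0,
        meal_spike_rate=1.5,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def aligned_small(small_cohort):
    return align_cohort(small_cohort, window=6, horizon_steps=1, test_points=48)


@pytest.fixture(scope="session")
def small_graph(small_cohort):
    series = []
    for rec in small_cohort:
        raw = rec.values[: len(rec.values) - 48]
        series.append((raw - raw.min()) / (raw.max() - raw.min()))
    _, graph = srgraph_from_series(series, k=3, record_ids=[r.patient_id for r in small_cohort])
    return graph


@pytest.fixture
def tiny_config():
    return HETERConfig(
        window=6,
        horizon_steps=1,
        k=3,
        gcn_hidden=8,
        conv_channels=4,
        conv_kernel=3,
        att_hidden=4,
        gru_hidden=8,
        mlp_hidden=4,
        smlp_hidden=4,
        dropout_g=0.0,
        dropout_co=0.0,
        dropout_o=0.0,
        seed=0,
    )


@pytest.fixture
def tiny_model(tiny_config, small_graph):
    params = HETERParams.initialize(tiny_config, small_graph.n_nodes)
    return params


def random_graph(rng, n, k):
    """Random directed top-K graph over n nodes (test helper)."""
    from heterbgp.srgraph import DistanceMatrix

    gamma = rng.random((n, n))
    gamma = (gamma + gamma.T) / 2
    np.fill_diagonal(gamma, 0.0)
    adjacency = topk_adjacency(DistanceMatrix(gamma, [str(i) for i in range(n)]), k)
    return build_srgraph(adjacency, k)


def make_record(values, patient_id="p0", diabetes_type="T1DM"):
    return CGMRecord(
        patient_id=patient_id,
        diabetes_type=diabetes_type,
        values=np.asarray(values, dtype=float),
    )
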