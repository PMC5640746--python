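import pytest

from carenet.network_build import BuildRule, DirectedNetwork, build_network
from carenet.network_metrics import metrics_table
from carenet.survey_io import SERVICE_TYPES, ServiceNode, analysis_set
from carenet.synthetic_data import SimulationConfig, generate_study


def make_network(n, edges, types=None, network_id="T1", participated=None):
    """Construct a DirectedNetwork directly from integer node labels."""
    if types is None:
        types = [SERVICE_TYPES[i % len(SERVICE_TYPES)] for i in range(n)]
    if participated is None:
        participated = [True] * n
    nodes = [
        ServiceNode(
            service_id=f"S{i}", network_id=network_id, service_type=types[i], participated=participated[i]
        )
        for i in range(n)
    ]
    edge_set = {(f"S{a}", f"S{b}") for a, b in edges}
    return DirectedNetwork(network_id=network_id, nodes=nodes, edges=edge_set, build_rule=BuildRule())


def complete_digraph(n, **kw):
    return make_network(n, [(a, b) for a in range(n) for b in range(n) if a != b], **kw)


def inward_star(n, hub=0, **kw):
    return make_network(n, [(i, hub) for i in range(n) if i != hub], **kw)


def random_digraph(n, rng, p=0.4, **kw):
    edges = [(a, b) for a in range(n) for b in range(n) if a != b and rng.random() < p]
    return make_network(n, edges, **kw)


def networks_from_study(study, threshold="sometimes_or_often", scope="participants_only"):
    by_net = {}
    for s in study.roster:
        by_net.setdefault(s.network_id, []).append(s)
    ties_by_net = {}
    for t in study.ties:
        ties_by_net.setdefault(t.network_id, []).append(t)
    return [
        build_network(by_net[n], ties_by_net.get(n, []), threshold=threshold, scope=scope)
        for n in sorted(by_net)
    ]


def fit_inputs(study):
    """(complete patients, per-network metric rows) under the main build rule."""
    rows, _ = metrics_table(networks_from_study(study))
    return analysis_set(study.patients), rows


@pytest.fixture(scope="session")
def default_study():
    """One default-configuration simulated study (19 networks x 80 patients)."""
    return generate_study(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_study_config():
    """A reduced study used where full scale adds nothing but runtime."""
    return SimulationConfig(
        n_networks=6,
        size_min=12,
        size_max=30,
        patients_per_network=40,
        cluster_size=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_study_config):
    return generate_study(small_study_config)
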