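import pytest

from dganet.network_io import AnnotationMap, WeightedNetwork, read_annotations, read_string_edges, restrict_to_annotated
from dganet.simulate import SyntheticSpec, generate, worked_example


def make_network(confidences, transform="one_minus"):
    """Build a WeightedNetwork from {(u, v): confidence}."""
    return WeightedNetwork.from_confidences(confidences, transform)


@pytest.fixture
def toy_net():
    # PQ hub with two side edges; confidences all above the default filter
    return make_network(
        {
            ("A", "B"): 950,
            ("A", "C"): 980,
            ("A", "E"): 910,
            ("B", "C"): 920,
            ("C", "D"): 999,
        }
    )


@pytest.fixture
def toy_ann():
    return AnnotationMap(
        [
            ("A", "d1"),
            ("A", "d2"),
            ("B", "d1"),
            ("B", "d3"),
            ("C", "d2"),
            ("D", "d3"),
            ("E", "d1"),
        ],
        disease_names={"d1": "disease one"},
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small planted-module dataset for fast pipeline tests."""
    spec = SyntheticSpec(
        n_genes=80, n_modules=5, module_size=12, n_diseases=30,
        p_intra=0.6, p_inter=0.02, dropout=0.3, seed=7,
    )
    return generate(spec, tmp_path_factory.mktemp("smallsyn"))


@pytest.fixture(scope="session")
def small_data(small_bundle):
    """(network, annotations) of the small bundle, filtered and restricted."""
    net = read_string_edges(small_bundle.network_path)
    ann = read_annotations(small_bundle.annotation_path)
    return restrict_to_annotated(net, ann)


@pytest.fixture(scope="session")
def example_paths(tmp_path_factory):
    return worked_example(tmp_path_factory.mktemp("example"))
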