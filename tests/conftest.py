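import pytest

from dsdmc import gate_library as gl
from dsdmc.network import build_network
from dsdmc.ctmc import build_ctmc


@pytest.fixture(scope="session")
def faulty_pair_model():
    spec = gl.transducer_pair(1, "T")
    net = build_network(spec)
    return build_ctmc(net, spec, label_config=gl.transducer_labels(1))


@pytest.fixture(scope="session")
def fixed_pair_model():
    spec = gl.transducer_pair(1, "T2")
    net = build_network(spec)
    return build_ctmc(net, spec, label_config=gl.transducer_labels(1))


@pytest.fixture(scope="session")
def faulty_pair_network():
    spec = gl.transducer_pair(1, "T")
    return spec, build_network(spec)
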