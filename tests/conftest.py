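import numpy as np
import pytest

import cloudcircuit as cc


def make_circuit(n_neurons=300, jitter=20.0, seed=5, mean_degree=25.0,
                 grid_bin=4.0):
    """Small wired circuit for unit tests: returns (spec, neurons,
    morphologies, targets, reference connectome)."""
    spec = cc.default_circuit_spec(n_neurons=n_neurons, jitter=jitter,
                                   seed=seed, grid_bin=grid_bin)
    neurons = cc.generate_neurons(spec)
    morphs = cc.instantiate_morphologies(neurons, spec)
    targets = cc.default_targets(neurons, spec, mean_degree=mean_degree)
    ref = cc.sample_reference_connectome(neurons, morphs, spec, targets, seed=seed)
    return spec, neurons, morphs, targets, ref


@pytest.fixture(scope="session")
def small_circuit():
    return make_circuit()


@pytest.fixture(scope="session")
def small_reference(small_circuit):
    spec, neurons, morphs, targets, ref = small_circuit
    return cc.assign_connection_attributes(ref, neurons, seed=17)


@pytest.fixture(scope="session")
def small_cloud(small_circuit, small_reference):
    spec = small_circuit[0]
    return cc.build_cloud_connectome(small_reference, spec, seed=5)


def random_digraph(rng, n, p):
    A = rng.random((n, n)) < p
    np.fill_diagonal(A, False)
    return A
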