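import numpy as np
import pytest

from cryosse import (
    TrainingConfig,
    build_toy_chain,
    build_unet,
    label_voxels,
    simulate_density,
    train,
)
from cryosse.synthetic import standard_fixture_spec, training_fixture_specs


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard helix-coil-strand chain with its map and labels."""
    spec = standard_fixture_spec(seed=0)
    chain = build_toy_chain(spec)
    density = simulate_density(chain, spec)
    labels = label_voxels(chain, density)
    return spec, chain, density, labels


@pytest.fixture(scope="session")
def training_pairs():
    """The two compact training chains with maps and ground-truth labels."""
    out = []
    for spec in training_fixture_specs(seed=0):
        chain = build_toy_chain(spec)
        density = simulate_density(chain, spec)
        labels = label_voxels(chain, density)
        out.append((chain, density, labels))
    return out


@pytest.fixture(scope="session")
def trained_network(training_pairs):
    """Network trained for the full 40 epochs on the 2-chain fixture.

    Session-scoped because the single-CPU training run dominates suite
    runtime; the loss log is returned for convergence checks.
    """
    pairs = [(density, labels) for _, density, labels in training_pairs]
    network = build_unet(seed=0)
    network, losses = train(pairs, network, TrainingConfig(epochs=40, seed=0))
    return network, losses
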