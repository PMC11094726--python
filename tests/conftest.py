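"""Shared fixtures.

The session-scoped chain (library -> fingerprints -> trained model -> mined
substructure networks) reproduces the package's reference study: a 2000-
compound synthetic library with four planted structural alerts, a one-hidden-
layer 512-neuron network trained with early stopping, and full per-neuron
substructure extraction.  It is built once and reused by the end-to-end
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from molscope.chem import Molecule, morgan_fingerprint
from molscope.network import NetConfig, TrainedModel, train
from molscope.synthetic import LibraryConfig, generate_library

LIBRARY_SEED = 11
SPLIT_SEED = 5
NET_SEED = 5


@pytest.fixture(scope="session")
def library2000():
    """Default study library: 2000 compounds, 4 planted alerts, ~50% positive."""
    return generate_library(LibraryConfig(n_compounds=2000, seed=LIBRARY_SEED))


@pytest.fixture(scope="session")
def fingerprints2000(library2000):
    return [morgan_fingerprint(m) for m in library2000]


@pytest.fixture(scope="session")
def split2000(library2000):
    rng = np.random.default_rng(SPLIT_SEED)
    order = rng.permutation(len(library2000))
    n_train, n_val = int(0.8 * len(order)), int(0.1 * len(order))
    return {
        "train": list(order[:n_train]),
        "val": list(order[n_train : n_train + n_val]),
        "test": list(order[n_train + n_val :]),
    }


@pytest.fixture(scope="session")
def model512(library2000, fingerprints2000, split2000):
    pairs = lambda idx: [(fingerprints2000[i], library2000[i].label) for i in idx]
    cfg = NetConfig.one_layer(hidden_size=512, seed=NET_SEED)
    return train(pairs(split2000["train"]), pairs(split2000["val"]), cfg)


@pytest.fixture
def nitrobenzene():
    return Molecule.from_smiles("O=[N+]([O-])c1ccccc1", "nitrobenzene")


@pytest.fixture
def hand_model():
    """2-input / 1-hidden / 1-output net: w=[1,-1], b_h=0.5, w_o=2, b_o=-1."""
    return TrainedModel.from_weights(
        weights=[np.array([[1.0], [-1.0]]), np.array([[2.0]])],
        biases=[np.array([0.5]), np.array([-1.0])],
    )
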