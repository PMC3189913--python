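import numpy as np
import pytest

import pantherin as pt

# holotype skull measurements (mm) used throughout the ratio tests
HOLOTYPE = {
    "CBL": 236.3,
    "greatest_skull_length": 264.0,
    "nasal_length": 81.6,
    "mandible_length": 167.8,
    "C1_height": 56.0,
    "P4_length": 31.7,
    "M1_length": 24.6,
}


@pytest.fixture(scope="session")
def holotype():
    return dict(HOLOTYPE)


@pytest.fixture(scope="session")
def six_taxon_tree():
    return pt.read_newick("((A,B),((C,D),(E,F)));")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


def random_matrix(rng, n_taxa, n_chars, n_states=3, p_missing=0.05):
    """Random multistate character matrix with occasional missing cells."""
    syms = np.array(list("0123456789"[:n_states]) + ["?"])
    probs = [(1 - p_missing) / n_states] * n_states + [p_missing]
    states = rng.choice(syms, size=(n_taxa, n_chars), p=probs)
    # ensure every character has at least one scored taxon
    for j in range(n_chars):
        if (states[:, j] == "?").all():
            states[rng.integers(0, n_taxa), j] = "0"
    taxa = [f"t{i}" for i in range(n_taxa)]
    return pt.CharacterMatrix(taxa=taxa, states=states)
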