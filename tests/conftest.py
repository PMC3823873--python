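import numpy as np
import pytest

import barcodegap as bg


@pytest.fixture(scope="session")
def skink_world():
    """The skink-like study dataset (current taxonomy, all discoveries)."""
    sset = bg.simulate_dataset(bg.get_preset("skink_current", seed=1))
    matrix = bg.build_matrix(sset)
    return sset, matrix


@pytest.fixture(scope="session")
def skink_1977(skink_world):
    """Historic-baseline view: specimens labelled under the 1977-style scheme."""
    sset, matrix = skink_world
    his = sset.taxonomies["historic"]
    ids = [i for i in matrix.ids if i in his.label_of]
    return sset, matrix.submatrix(ids)


@pytest.fixture(scope="session")
def gapped_world():
    sset = bg.simulate_dataset(bg.get_preset("gapped", seed=1))
    matrix = bg.build_matrix(sset)
    return sset, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(20130)


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def mutate(rng, seq, n_transitions=0, n_transversions=0, n_gaps=0):
    """Apply an exact number of edits at distinct sites (test helper)."""
    ts_partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_partner = {"A": "C", "G": "T", "C": "G", "T": "A"}
    sites = rng.choice(len(seq), size=n_transitions + n_transversions + n_gaps,
                       replace=False)
    out = list(seq)
    for k, site in enumerate(sites):
        if k < n_transitions:
            out[site] = ts_partner[out[site]]
        elif k < n_transitions + n_transversions:
            out[site] = tv_partner[out[site]]
        else:
            out[site] = "-"
    return "".join(out)
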