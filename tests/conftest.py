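import numpy as np
import pytest

from protdna_korr.alignments import PairRecord, PairedAlignmentSet
from protdna_korr.substitution import blosum_transition_probs, identity_model


def make_set(pairs, weights=None):
    """Build a PairedAlignmentSet from (tf_row, site_row) string pairs."""
    recs = []
    for k, (tf_row, site_row) in enumerate(pairs):
        w = 1.0 if weights is None else weights[k]
        recs.append(PairRecord(f"tf{k}", f"s{k}", tf_row, site_row, w))
    return PairedAlignmentSet(recs)


def random_set(rng, n_records=12, n_prot=5, n_site=4, weighted=True, gap_rate=0.0):
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    nts = list("ACGT")
    pairs, weights = [], []
    for _ in range(n_records):
        tf = "".join(
            "-" if rng.random() < gap_rate else rng.choice(aas) for _ in range(n_prot)
        )
        st = "".join(
            "-" if rng.random() < gap_rate else rng.choice(nts) for _ in range(n_site)
        )
        pairs.append((tf, st))
        weights.append(float(rng.uniform(0.2, 2.0)) if weighted else 1.0)
    return make_set(pairs, weights)


@pytest.fixture(scope="session")
def blosum_model():
    return blosum_transition_probs("BLOSUM45", kappa=0.5)


@pytest.fixture(scope="session")
def id_model():
    return identity_model(kappa=0.5)


@pytest.fixture(scope="session")
def kappa0_model():
    return identity_model(kappa=0.0)
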