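import numpy as np
import pytest

import adspeech as ad


@pytest.fixture(scope="session")
def inv318():
    """The packaged 317-syllable inventory (token space 318)."""
    return ad.default_inventory()


@pytest.fixture()
def tiny_inv():
    """A 4-syllable inventory (token space 5) for hand-traceable cases."""
    return ad.build_inventory(["a", "b", "c", "d"], "<sil>")


@pytest.fixture(scope="session")
def small_cohort(inv318):
    """A reduced two-class cohort for fast engine tests (5+5 subjects × 2)."""
    spec = ad.CohortSpec(n_subjects_per_class=5, tests_per_subject=2, seed=11)
    spec.ch.mean_length = 60
    spec.ad.mean_length = 30
    seqs, _ = ad.generate_cohort(spec, inv318)
    return seqs


def rng(seed=0):
    return np.random.default_rng(seed)
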