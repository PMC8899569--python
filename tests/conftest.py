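import numpy as np
import pytest

from alleledit.fixtures import kcnq4_w276s_amplicon
from alleledit.guides import enumerate_guides
from alleledit.reference import derive_wt_sequence


@pytest.fixture(scope="session")
def ref():
    """Canonical mutant-allele donor amplicon (marker @41, pathogenic @61)."""
    return kcnq4_w276s_amplicon()


@pytest.fixture(scope="session")
def wt_seq(ref):
    return derive_wt_sequence(ref)


@pytest.fixture(scope="session")
def mutant_guide(ref):
    """A mutant-overlapping guide on the fixture (deterministic first hit)."""
    return enumerate_guides(ref, allele="mutant", strands="both",
                            require_variant_overlap=True)[0]


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
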