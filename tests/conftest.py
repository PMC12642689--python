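import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def toy_alignment():
    """Four taxa, five codon columns, one gap codon, no stops."""
    from selstruct.seqdata import CodonAlignment

    return CodonAlignment(
        ["t1", "t2", "t3", "t4"],
        [
            "ATGGCTAAAGGGTGC",
            "ATGGCCAAAGGGTGC",
            "ATG---AAAGGCTGC",
            "ATGGCTAGAGGGTGT",
        ],
    )


@pytest.fixture
def quartet_sim():
    """Small simulated alignment on a 4-taxon tree with known truth."""
    from selstruct.synthetic_data import SimSpec, simulate_codon_alignment

    return simulate_codon_alignment(
        SimSpec(seed=42, n_codons=40, kappa=2.0, n_taxa=4, depth=0.6,
                site_class_plan=[(0.3, 1.0)])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
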