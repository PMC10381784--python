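import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from g4cons.dataset_io import Promoter, PromoterSet
from g4cons.synthetic_data import SimConfig, generate_order


def random_dna(rng: np.random.Generator, n: int, p_g: float = 0.25) -> str:
    """Random sequence with adjustable G content (rest uniform)."""
    q = (1 - p_g) / 3
    return "".join(rng.choice(list("GACT"), size=n, p=[p_g, q, q, q]))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230629)


@pytest.fixture()
def small_set() -> PromoterSet:
    """Five identical 300-nt promoters (a trivially alignable order)."""
    seq = (
        "ATCTATCCATGATTCAATCGCATTCAAGACTGGATAGCTTCATCAGAGTT"
        "GACTTATTGTCAGTCCTAAGGGTTAGGGTTAGGGTTAGGGATCCTTCTAT"
        "CCTTTGACTTCCAATCACTAAACTGATTATCAGTCCATGATAGCATTAGC"
        "CATTGAGTCCTTAGATCTATTGCACTTAATTAGACTTCGATTCCATGAGA"
        "TCAGGATCCTATTTACCAGTTACTCAGTCATTATCTATGACTCCTAATGA"
        "GTCTCAGATTACTGATTACCAGTATTCCTAGTCCATTGATAGCTTCAGAT"
    )
    promoters = [
        Promoter(f"SynA{c}sim", "Syn", seq) for c in "abcde"
    ]
    return PromoterSet("Syn", promoters)


@pytest.fixture(scope="session")
def noisy_order():
    """One simulated order at the default study conditions (5% divergence)."""
    return generate_order(SimConfig(seed=11))
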