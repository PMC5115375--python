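import random

import pytest

from beaconlogic import CIRCUIT_KINDS, Strand, StrandSet, design_strands, default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def designed_sets():
    """One designer-generated strand set per circuit kind, seed 1."""
    return {kind: design_strands(kind, seed=1) for kind in CIRCUIT_KINDS}


def random_strand(rng: random.Random, name: str, lo: int = 12, hi: int = 25,
                  role: str = "input") -> Strand:
    length = rng.randint(lo, hi)
    return Strand(name, "".join(rng.choice("ACGT") for _ in range(length)), role)


def random_strand_set(rng: random.Random, n_strands: int) -> StrandSet:
    strands = [random_strand(rng, "MB", 16, 30, role="beacon")]
    strands += [random_strand(rng, f"S{i}") for i in range(n_strands - 1)]
    return StrandSet(strands)
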