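import numpy as np
import pytest

from cascadescope.duplex_model import Spacer
from cascadescope import synthetic_data as synth


def random_spacer(seed: int, length: int = 32, sid: str | None = None) -> Spacer:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Spacer(id=sid or f"sp{seed}", sequence=seq)


@pytest.fixture
def spacer() -> Spacer:
    """A fixed random 32-nt spacer (non-repetitive, unlike e.g. (ACGT)x8)."""
    return random_spacer(101, sid="sp8")


@pytest.fixture
def planted_genome(spacer):
    """A 6-kb genome with four planted sites of known profile.

    Sites: full-match AAG (on-target analogue), 5-nt seed AAG on the minus
    strand, full-match CCG (dead PAM), and a 4-nt seed AAG (undetectable).
    """
    genome = {"chr": synth.make_genome(6000, 0.5, seed=11)}
    specs = [
        synth.PlantSpec("sp8", "AAG", frozenset(range(1, 33)), "chr", 1000, "+"),
        synth.PlantSpec("sp8", "AAG", frozenset(range(1, 6)), "chr", 2500, "-"),
        synth.PlantSpec("sp8", "CCG", frozenset(range(1, 33)), "chr", 4000, "+"),
        synth.PlantSpec("sp8", "AAG", frozenset(range(1, 5)), "chr", 5000, "+"),
    ]
    genome, truth = synth.plant_sites(genome, spacer, specs)
    truth.weights = [1000.0, 300.0, 50.0, 200.0]
    return genome, truth
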