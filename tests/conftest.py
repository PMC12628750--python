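import numpy as np
import pytest

from pentaplex.repeat_model import RepeatMotif

PENTAMERS = ("TTTTA", "TTTCA", "TTGTA", "TTCCA")
COMPOSITE = "TTTTATTTTATTTCA"

# printed repeat-primed PCR primer used as a worked string example
RP_PRIMER = "TACGCATCCCAGTTTGAGACGTTGTATTGTATTGTATTGTATTGTATTGTA"

FAME3_REGION = "chr5:10356339-10356411"


@pytest.fixture
def pentamers():
    return tuple(RepeatMotif(m) for m in PENTAMERS)


@pytest.fixture
def screen_motifs():
    return (RepeatMotif("TTTTA"), RepeatMotif("TTTCA"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_read(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


def plant_tract(rng, length, motif, tract_bp, at=None):
    """Random read with a pure truncated-copy tract of ``motif`` planted in it."""
    tract = (motif * (tract_bp // len(motif) + 2))[:tract_bp]
    if at is None:
        at = int(rng.integers(0, length - tract_bp + 1))
    bg = random_read(rng, length)
    return bg[:at] + tract + bg[at + tract_bp :]
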