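import numpy as np
import pytest

from genomesig import seq_io


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fragment(rng, length=1000, n_fraction=0.0, species="test", start=0):
    """A random fragment, optionally salted with N positions."""
    codes = rng.integers(0, 4, size=length)
    if n_fraction > 0:
        n_sites = rng.random(length) < n_fraction
        codes[n_sites] = 4
    seq = "".join("ACGTN"[c] for c in codes)
    return seq_io.Fragment(
        species_label=species,
        sequence_id="rand",
        start=start,
        end=start + length,
        sequence=seq,
        n_count=seq.count("N"),
        case_mask=np.zeros(length, dtype=bool),
    )


def make_fragment(seq, species="test"):
    return seq_io.Fragment(
        species_label=species,
        sequence_id="s",
        start=0,
        end=len(seq),
        sequence=seq,
        n_count=seq.upper().count("N"),
        case_mask=np.array([c.islower() for c in seq]),
    )
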