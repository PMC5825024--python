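"""Low-level nucleotide-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Full 3' adapter used throughout; trimming keys on its first 7 nt (TGGAATT).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER_SEED_LENGTH = 7


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    """True if ``seq`` is non-empty and contains only A/C/G/T."""
    return bool(seq) and not set(seq) - set(DNA_ALPHABET)


def encode(seq: str) -> np.ndarray:
    """View a nucleotide string as a uint8 byte array (no copy of content)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int, forbidden: str | None = None) -> str:
    """Random DNA string; resampled until ``forbidden`` does not occur.

    Used to keep the adapter seed out of reference/background sequence, so
    that leftmost-seed adapter trimming is unambiguous on error-free reads.
    """
    for _ in range(1000):
        seq = "".join(rng.choice(list(DNA_ALPHABET), size=length))
        if forbidden is None or forbidden not in seq:
            return seq
    raise RuntimeError("could not sample a sequence avoiding the forbidden motif")
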