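"""Oligonucleotide frequency vectors over degenerate complementary k-mer sets.

Only one strand of a double helix is deposited in sequence databases, and the
deposited strand is arbitrary.  Summing each k-mer with its reverse complement
("AAC+GTT") removes that arbitrariness: the resulting degenerate composition
vector is identical for a fragment and its reverse complement.  The degenerate
sets for k = 2, 3, 4 contain 10, 32 and 136 classes and are called DegDi,
DegTri and DegTetra.

Counting is case-insensitive (soft-masking carries no compositional meaning
here) and uses overlapping windows of step 1.  Windows containing an N are
skipped, and frequencies are divided by the number of N-free windows, so a
vector always sums to 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .seq_io import Fragment, encode, reverse_complement

BASES = "ACGT"


class ZeroValidWindowsError(ValueError):
    """A fragment had no N-free k-windows; the caller should drop it."""


def _all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


@dataclass(frozen=True, eq=False)
class DegenerateKeyMap:
    """Ordered partition of all 4^k words into (possibly degenerate) classes.

    In the degenerate case every class is {w, revcomp(w)} labelled
    ``"w+revcomp(w)"`` with w the lexicographically smaller member, or just
    ``"w"`` for a self-complementary word.  Classes are ordered
    lexicographically by label, fixing the column order of every signature
    matrix built from this map.
    """

    k: int
    degenerate: bool
    keys: tuple[str, ...]
    member_map: dict[str, str] = field(repr=False)
    #: 4^k array mapping a word's base-4 code to its class index
    class_index: np.ndarray = field(repr=False)

    @property
    def n_classes(self) -> int:
        return len(self.keys)

    def members(self, label: str) -> tuple[str, ...]:
        """The member words of a class label."""
        return tuple(w for w in label.split("+"))


@lru_cache(maxsize=None)
def build_key_map(k: int, degenerate: bool = True) -> DegenerateKeyMap:
    """Build the key map for word length ``k`` (1 <= k <= 6)."""
    if not 1 <= k <= 6:
        raise ValueError(f"k must be in 1..6, got {k}")
    words = _all_kmers(k)
    member_map: dict[str, str] = {}
    if degenerate:
        for w in words:
            rc = reverse_complement(w)
            member_map[w] = w if w == rc else f"{min(w, rc)}+{max(w, rc)}"
    else:
        member_map = {w: w for w in words}
    keys = tuple(sorted(set(member_map.values())))
    key_pos = {label: i for i, label in enumerate(keys)}
    class_index = np.array([key_pos[member_map[w]] for w in words], dtype=np.int64)
    return DegenerateKeyMap(
        k=k, degenerate=degenerate, keys=keys, member_map=member_map,
        class_index=class_index,
    )


@dataclass
class OligoVector:
    """Frequency vector of one fragment over a key map's classes."""

    species_label: str
    fragment_id: str
    k: int
    degenerate: bool
    freqs: dict[str, float]
    valid_windows: int

    def as_array(self, key_map: DegenerateKeyMap) -> np.ndarray:
        return np.array([self.freqs[label] for label in key_map.keys])


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 index of every k-window plus a validity mask (no N inside)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    clipped = np.minimum(codes, 3).astype(np.int64)
    is_n = codes == 4
    for offset in range(k):
        idx = idx * 4 + clipped[offset : offset + n]
        valid &= ~is_n[offset : offset + n]
    return idx, valid


def class_counts(codes: np.ndarray, key_map: DegenerateKeyMap) -> tuple[np.ndarray, int]:
    """Raw per-class counts and the number of valid windows for one sequence."""
    idx, valid = _window_codes(codes, key_map.k)
    word_counts = np.bincount(idx[valid], minlength=4 ** key_map.k)
    counts = np.bincount(
        key_map.class_index, weights=word_counts, minlength=key_map.n_classes
    )
    return counts, int(valid.sum())


def count_oligos(fragment: Fragment, key_map: DegenerateKeyMap) -> OligoVector:
    """Count class frequencies in one fragment.

    Frequencies are each class's window count divided by the number of N-free
    windows, so they sum to 1.  A self-complementary word is counted once per
    genomic occurrence (it is not doubled when its class is collapsed).

    Raises :class:`ZeroValidWindowsError` when the fragment has no N-free
    window; callers drop such fragments and log them.
    """
    counts, valid = class_counts(fragment.codes, key_map)
    if valid == 0:
        raise ZeroValidWindowsError(
            f"fragment {fragment.sequence_id}:{fragment.start}-{fragment.end} "
            "has no N-free windows"
        )
    freqs = dict(zip(key_map.keys, counts / valid))
    return OligoVector(
        species_label=fragment.species_label,
        fragment_id=f"{fragment.sequence_id}:{fragment.start}-{fragment.end}",
        k=key_map.k,
        degenerate=key_map.degenerate,
        freqs=freqs,
        valid_windows=valid,
    )


def mono_composition(fragment: Fragment | str) -> tuple[dict[str, float], float]:
    """Mononucleotide frequencies over non-N positions, plus the G+C fraction.

    Raises :class:`ZeroValidWindowsError` for an all-N fragment.
    """
    codes = encode(fragment) if isinstance(fragment, str) else fragment.codes
    counts = np.bincount(codes, minlength=5)[:4]
    total = counts.sum()
    if total == 0:
        raise ZeroValidWindowsError("fragment is all N")
    freqs = counts / total
    comp = dict(zip(BASES, freqs))
    return comp, float(freqs[1] + freqs[2])


def signature_matrix(
    fragments: list[Fragment], key_map: DegenerateKeyMap
) -> tuple[pd.DataFrame, list[Fragment]]:
    """Frequency matrix (rows = fragments, columns = key-map classes).

    Fragments with zero valid windows are dropped; the retained fragments are
    returned alongside so rows and fragments stay aligned.  The frame carries
    ``species_label`` and ``gc_fraction`` as extra columns.
    """
    rows, kept = [], []
    for frag in fragments:
        try:
            vec = count_oligos(frag, key_map)
        except ZeroValidWindowsError:
            continue
        _, gc = mono_composition(frag)
        row = dict(vec.freqs)
        row["species_label"] = frag.species_label
        row["gc_fraction"] = gc
        rows.append(row)
        kept.append(frag)
    frame = pd.DataFrame(rows, columns=list(key_map.keys) + ["species_label", "gc_fraction"])
    return frame, kept
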