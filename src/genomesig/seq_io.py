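"""Soft-masked FASTA input, fixed-length fragmentation, repeat/unique partitioning.

Genome assemblies distributed through browser databases mark repeat-masked
sequence (RepeatMasker, Tandem Repeats Finder) in lowercase and unique sequence
in uppercase.  This module reads such files with case preserved, cuts each
record into non-overlapping fixed-length windows (default 100 kb), applies the
standard quality filter that discards windows with more than 20% undetermined
(N) bases, and can partition a genome into artificial "unique" and "repeat"
sub-genomes by concatenating the uppercase and lowercase runs separately.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: the 10-letter residue alphabet kept on read; anything else becomes N/n
ALPHABET = set("ACGTNacgtn")

_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i

_LOWER_TABLE = np.zeros(256, dtype=bool)
for _b in "acgtn":
    _LOWER_TABLE[ord(_b)] = True


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string as uint8 codes A=0, C=1, G=2, T=3, N/other=4."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def lowercase_mask(sequence: str) -> np.ndarray:
    """Boolean array, True where a position is lowercase (repeat-masked)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _LOWER_TABLE[raw]


class FastaParseError(ValueError):
    """Raised when an input file is not parseable as FASTA."""


@dataclass
class GenomeSequence:
    """A soft-masked assembly: a species label plus its sequence records."""

    species_label: str
    records: list[tuple[str, str]] = field(default_factory=list)
    #: number of non-N IUPAC ambiguity codes replaced by N on read
    ambiguity_count: int = 0

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class Fragment:
    """One fixed-length genomic window.

    ``case_mask`` is True where the source assembly was lowercase
    (repeat-masked); ``n_count`` counts N/n residues.
    """

    species_label: str
    sequence_id: str
    start: int
    end: int
    sequence: str
    n_count: int
    case_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("fragment coordinates do not match sequence length")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def repeat_fraction(self) -> float:
        return float(self.case_mask.mean())

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _sanitize(seq: str) -> tuple[str, int]:
    """Map residues outside {A,C,G,T,N,a,c,g,t,n} to N (n if lowercase)."""
    bad = [c for c in set(seq) if c not in ALPHABET]
    if not bad:
        return seq, 0
    n_replaced = sum(seq.count(c) for c in bad)
    table = {c: ("n" if c.islower() else "N") for c in bad}
    return seq.translate(str.maketrans(table)), n_replaced


def read_fasta(path: str | Path, species_label: str) -> GenomeSequence:
    """Read a soft-masked FASTA file, preserving case.

    IUPAC ambiguity codes other than N are replaced by N and counted on the
    returned :class:`GenomeSequence`; empty records are dropped.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`FastaParseError` for content that is not FASTA.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno} is not FASTA (expected '>' header first)"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty file, no FASTA records")

    genome = GenomeSequence(species_label=species_label)
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if not seq:
            continue
        seq, n_replaced = _sanitize(seq)
        genome.ambiguity_count += n_replaced
        genome.records.append((record.id, seq))
    if genome.ambiguity_count:
        log.info(
            "%s: replaced %d ambiguity codes by N", species_label, genome.ambiguity_count
        )
    return genome


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA, preserving soft-mask case."""
    with open(path, "w") as out:
        for rec_id, seq in genome.records:
            out.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


@dataclass
class FragmentFilterLog:
    """Bookkeeping for the N-content filter and trailing-window discards."""

    n_filtered: int = 0
    trailing_bp_discarded: int = 0


def fragment_genome(
    genome: GenomeSequence,
    window_bp: int = 100_000,
    max_n_fraction: float = 0.20,
    filter_log: FragmentFilterLog | None = None,
) -> list[Fragment]:
    """Tile each record with non-overlapping windows and apply the N filter.

    Windows start at position 0 of every record; a trailing window shorter
    than ``window_bp`` is discarded (frequency vectors must be comparable
    across fragments of one fixed length).  A window whose N fraction is
    strictly greater than ``max_n_fraction`` is omitted — a window with
    exactly the threshold fraction is retained.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    filter_log = filter_log if filter_log is not None else FragmentFilterLog()
    fragments: list[Fragment] = []
    max_n = max_n_fraction * window_bp
    for rec_id, seq in genome.records:
        n_windows = len(seq) // window_bp
        filter_log.trailing_bp_discarded += len(seq) - n_windows * window_bp
        codes = encode(seq)
        lower = lowercase_mask(seq)
        for w in range(n_windows):
            start, end = w * window_bp, (w + 1) * window_bp
            n_count = int((codes[start:end] == 4).sum())
            if n_count > max_n:
                filter_log.n_filtered += 1
                continue
            fragments.append(
                Fragment(
                    species_label=genome.species_label,
                    sequence_id=rec_id,
                    start=start,
                    end=end,
                    sequence=seq[start:end],
                    n_count=n_count,
                    case_mask=lower[start:end],
                )
            )
    if filter_log.n_filtered:
        log.info(
            "%s: %d windows dropped by the %d%% N filter",
            genome.species_label,
            filter_log.n_filtered,
            round(100 * max_n_fraction),
        )
    return fragments


def split_by_case(genome: GenomeSequence) -> tuple[GenomeSequence, GenomeSequence]:
    """Partition a soft-masked genome into unique and repeat sub-genomes.

    All uppercase runs are concatenated (across records, in genomic order)
    into a single artificial "unique" record and all lowercase runs into a
    single "repeat" record, which downstream fragmentation then cuts into
    fixed-length windows.  N/n residues follow their case.  An all-uppercase
    genome yields an empty repeat partition.
    """
    unique_parts: list[str] = []
    repeat_parts: list[str] = []
    n_runs = 0
    for _, seq in genome.records:
        lower = lowercase_mask(seq)
        if len(lower) == 0:
            continue
        boundaries = np.flatnonzero(np.diff(lower.view(np.int8))) + 1
        edges = np.concatenate(([0], boundaries, [len(seq)]))
        n_runs += len(edges) - 1
        for a, b in zip(edges[:-1], edges[1:]):
            (repeat_parts if lower[a] else unique_parts).append(seq[a:b])
    log.debug("%s: %d case runs", genome.species_label, n_runs)
    unique = GenomeSequence(
        species_label=genome.species_label,
        records=[("unique", "".join(unique_parts))] if unique_parts else [("unique", "")],
    )
    repeat = GenomeSequence(
        species_label=genome.species_label,
        records=[("repeat", "".join(repeat_parts))] if repeat_parts else [("repeat", "")],
    )
    return unique, repeat


def fragment_manifest(fragments: Iterable[Fragment]) -> pd.DataFrame:
    """Tabular manifest of retained fragments (TSV-ready)."""
    return pd.DataFrame(
        {
            "species": f.species_label,
            "sequence_id": f.sequence_id,
            "start": f.start,
            "end": f.end,
            "n_count": f.n_count,
            "repeat_fraction": f.repeat_fraction,
        }
        for f in fragments
    )
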