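"""Sliding-window CpG-island detection and inside/outside CG-level contrast.

CpG islands are short CG-rich, CG-unsuppressed stretches (canonically GC%
>= 50, CG observed/expected >= 0.6, length >= 200 bp) associated with
promoters; cytosines inside them are largely unmethylated, so deamination-
driven CG loss acts mainly *outside* islands.  Contrasting the normalized CG
level inside vs outside islands therefore isolates the methylation-exposed
portion of a genome.

Detection follows the classical sliding-window recipe (as in EMBOSS
``newcpgreport``): a window of 100 bp slides by 1 bp; positions whose window
passes both thresholds are island candidates; maximal runs of candidate
positions are merged into intervals (spanning the union of their windows),
and intervals shorter than the minimum length are discarded.  Windows
containing N never qualify, so N runs break candidate regions.  Merged
intervals are finally re-checked against the thresholds at the island level,
which keeps every reported island individually GC-rich and CG-unsuppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition_stats import normalized_level
from .seq_io import GenomeSequence, encode


@dataclass
class IslandParams:
    window: int = 100
    shift: int = 1
    min_length: int = 200
    min_gc: float = 0.5
    min_oe: float = 0.6


@dataclass
class IslandSet:
    """Non-overlapping, sorted island intervals (0-based, half-open)."""

    intervals: list[tuple[str, int, int]]
    params: IslandParams = field(default_factory=IslandParams)

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as out:
            for seq_id, start, end in self.intervals:
                out.write(f"{seq_id}\t{start}\t{end}\tCpG_island\n")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intervals, columns=["sequence_id", "start", "end"]
        )


def _window_stats(codes: np.ndarray, window: int) -> tuple[np.ndarray, ...]:
    """Per-window C count, G count, CG count and N count via cumulative sums."""
    n = len(codes) - window + 1
    is_c = (codes == 1).astype(np.int64)
    is_g = (codes == 2).astype(np.int64)
    is_n = (codes == 4).astype(np.int64)
    is_cg = ((codes[:-1] == 1) & (codes[1:] == 2)).astype(np.int64)

    def windowed(x: np.ndarray, width: int) -> np.ndarray:
        c = np.concatenate(([0], np.cumsum(x)))
        return c[width:] - c[:-width]

    c_cnt = windowed(is_c, window)[:n]
    g_cnt = windowed(is_g, window)[:n]
    n_cnt = windowed(is_n, window)[:n]
    # a window of length `window` holds window-1 dinucleotide starts
    cg_cnt = windowed(is_cg, window - 1)[:n]
    return c_cnt, g_cnt, cg_cnt, n_cnt


def _interval_passes(codes: np.ndarray, params: IslandParams) -> bool:
    c = int((codes == 1).sum())
    g = int((codes == 2).sum())
    length = len(codes)
    if c == 0 or g == 0:
        return False
    gc = (c + g) / length
    cg = int(((codes[:-1] == 1) & (codes[1:] == 2)).sum())
    oe = cg / (c * g / length)
    return gc >= params.min_gc and oe >= params.min_oe


def detect_islands(
    sequence: str,
    sequence_id: str = "seq",
    window: int = 100,
    shift: int = 1,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> IslandSet:
    """Detect CpG islands in one sequence.

    The expected CG frequency of a window is C_count * G_count / window, the
    convention used by sliding-window island finders.  A sequence shorter
    than the window yields an empty island set.
    """
    params = IslandParams(window, shift, min_length, min_gc, min_oe)
    codes = encode(sequence)
    n = len(codes) - window + 1
    if n <= 0:
        return IslandSet(intervals=[], params=params)
    c_cnt, g_cnt, cg_cnt, n_cnt = _window_stats(codes, window)
    with np.errstate(invalid="ignore", divide="ignore"):
        gc_ok = (c_cnt + g_cnt) >= min_gc * window
        expected = c_cnt * g_cnt / window
        oe_ok = np.where(expected > 0, cg_cnt >= min_oe * expected, False)
    candidate = gc_ok & oe_ok & (n_cnt == 0)
    starts = np.arange(0, n, shift)
    candidate = candidate[starts]

    intervals: list[tuple[str, int, int]] = []
    run_start = None
    prev = None
    for pos, ok in zip(starts, candidate):
        if ok and run_start is None:
            run_start = pos
        elif not ok and run_start is not None:
            intervals.append((sequence_id, int(run_start), int(prev + window)))
            run_start = None
        if ok:
            prev = pos
    if run_start is not None:
        intervals.append((sequence_id, int(run_start), int(prev + window)))

    kept = [
        (sid, a, b)
        for sid, a, b in intervals
        if b - a >= min_length and _interval_passes(codes[a:b], params)
    ]
    return IslandSet(intervals=kept, params=params)


def detect_islands_genome(genome: GenomeSequence, **kwargs) -> IslandSet:
    """Run island detection over every record of a genome."""
    intervals: list[tuple[str, int, int]] = []
    params = IslandParams(**kwargs) if kwargs else IslandParams()
    for rec_id, seq in genome.records:
        found = detect_islands(seq, sequence_id=rec_id, **kwargs)
        intervals.extend(found.intervals)
        params = found.params
    return IslandSet(intervals=intervals, params=params)


def island_contrast(
    genome: GenomeSequence, islands: IslandSet
) -> tuple[float, float | None]:
    """Normalized CG level inside vs outside the islands.

    Inside is computed on the concatenation of island intervals, outside on
    their complement; together they partition every base pair exactly once.
    Returns ``(inside_level, outside_level)``; a side with no sequence (or
    an empty island set, for the inside) raises ``UndefinedLevelError`` via
    the level computation, except the fully-covered case where outside is
    returned as None.
    """
    by_record: dict[str, list[tuple[int, int]]] = {}
    for seq_id, start, end in islands.intervals:
        by_record.setdefault(seq_id, []).append((start, end))

    inside_parts: list[str] = []
    outside_parts: list[str] = []
    for rec_id, seq in genome.records:
        pos = 0
        for start, end in sorted(by_record.get(rec_id, [])):
            if start > pos:
                outside_parts.append(seq[pos:start])
            inside_parts.append(seq[start:end])
            pos = end
        if pos < len(seq):
            outside_parts.append(seq[pos:])

    from .composition_stats import UndefinedLevelError

    if not inside_parts:
        raise UndefinedLevelError("no islands: inside level undefined")
    inside = normalized_level(inside_parts, {"CG"})
    if not any(outside_parts):
        return inside, None
    outside = normalized_level(outside_parts, {"CG"})
    return inside, outside
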