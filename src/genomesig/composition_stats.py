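"""Genome-level CG suppression statistics and the 5-methylcytosine criteria.

Vertebrate genomes are depleted of the CG dinucleotide because cytosine in a
methylated CG deaminates to thymine, steadily converting CG to TG (or CA on
the other strand).  The statistics here quantify that footprint:

* ``normalized_level`` — the observed frequency of an oligonucleotide set
  divided by the frequency expected from mononucleotide composition alone
  (the observed/expected, or relative-abundance, level).  Unlike the raw
  frequency this is insensitive to genome G+C%.
* ``dinucleotide_ratio`` — classical single-strand ratios such as CpG/GpC,
  CA/AC and TG/GT.
* ``simmen_criteria`` — four genome-level regularities diagnostic of
  5-methylcytosine mutational pressure: (i) CG deficit, (ii) TG and CA
  excess, (iii) positive correlation of local CG relative abundance with
  local G+C% (high-G+C DNA melts less, deaminates less), and (iv) negative
  correlation of local CG with local TG and CA relative abundance.

Counts are pooled over fragments (weighting by each fragment's N-free
window count) rather than averaging per-fragment ratios, which avoids
small-denominator noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kmer_signature import BASES, build_key_map, class_counts
from .seq_io import Fragment, encode

#: below this |level - 1| margin a genome-level excess/deficit flag is not
#: asserted; absorbs sampling noise on null (bias-free) genomes
LEVEL_MARGIN = 0.02


class UndefinedLevelError(ValueError):
    """Observed or expected frequency vanished; the statistic is undefined."""


def _codes_of(item: Fragment | str) -> np.ndarray:
    return encode(item) if isinstance(item, str) else item.codes


def _pooled_counts(
    items: Iterable[Fragment | str], k: int
) -> tuple[np.ndarray, int, np.ndarray, int]:
    """Pooled k-mer counts/windows and mononucleotide counts/total."""
    key_map = build_key_map(k, degenerate=False)
    kmer_counts = np.zeros(4**k)
    windows = 0
    mono_counts = np.zeros(4)
    mono_total = 0
    for item in items:
        codes = _codes_of(item)
        counts, valid = class_counts(codes, key_map)
        kmer_counts += counts
        windows += valid
        mc = np.bincount(codes, minlength=5)[:4]
        mono_counts += mc
        mono_total += int(mc.sum())
    return kmer_counts, windows, mono_counts, mono_total


def _word_index(word: str) -> int:
    idx = 0
    for base in word:
        idx = idx * 4 + BASES.index(base)
    return idx


def normalized_level(
    items: Sequence[Fragment | str], oligo_set: Iterable[str]
) -> float:
    """Observed/expected level of a word set, pooled over fragments.

    ``oligo_set`` is an explicit word list of one common length, e.g.
    ``{"CG"}``, ``{"CC", "GG"}`` or ``{"CCCC", "GGGG"}``.  Observed is the
    summed frequency of the member words over pooled N-free windows;
    expected is the sum over members of the product of pooled mononucleotide
    frequencies.
    """
    words = sorted(set(w.upper() for w in oligo_set))
    if not words:
        raise ValueError("empty oligo_set")
    k = len(words[0])
    if any(len(w) != k for w in words):
        raise ValueError("all words in oligo_set must share one length")
    kmer_counts, windows, mono_counts, mono_total = _pooled_counts(items, k)
    if windows == 0 or mono_total == 0:
        raise UndefinedLevelError("no valid windows in input")
    pi = mono_counts / mono_total
    observed = sum(kmer_counts[_word_index(w)] for w in words) / windows
    expected = sum(np.prod([pi[BASES.index(b)] for b in w]) for w in words)
    if expected == 0:
        raise UndefinedLevelError(f"expected frequency of {words} is zero (missing base)")
    return float(observed / expected)


def dinucleotide_ratio(
    items: Sequence[Fragment | str], numerator: str, denominator: str
) -> float:
    """Single-strand frequency ratio of two dinucleotides (e.g. CG/GC)."""
    if len(numerator) != 2 or len(denominator) != 2:
        raise ValueError("numerator and denominator must be dinucleotides")
    kmer_counts, windows, _, _ = _pooled_counts(items, 2)
    if windows == 0:
        raise UndefinedLevelError("no valid dinucleotide windows in input")
    num = kmer_counts[_word_index(numerator.upper())]
    den = kmer_counts[_word_index(denominator.upper())]
    if den == 0:
        raise UndefinedLevelError(f"zero {denominator} count in input")
    return float(num / den)


def fragment_oe_table(fragments: Sequence[Fragment | str]) -> pd.DataFrame:
    """Per-fragment ("local") G+C% and CG/TG/CA observed-expected levels."""
    rows = []
    for idx, frag in enumerate(fragments):
        codes = _codes_of(frag)
        key_map = build_key_map(2, degenerate=False)
        counts, windows = class_counts(codes, key_map)
        mono = np.bincount(codes, minlength=5)[:4]
        total = mono.sum()
        if windows == 0 or total == 0:
            continue
        pi = mono / total
        def oe(word: str) -> float:
            expected = pi[BASES.index(word[0])] * pi[BASES.index(word[1])]
            if expected == 0:
                return np.nan
            return counts[_word_index(word)] / windows / expected
        rows.append(
            {
                "fragment": idx,
                "gc_fraction": float(pi[1] + pi[2]),
                "CG_oe": oe("CG"),
                "TG_oe": oe("TG"),
                "CA_oe": oe("CA"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class Criterion:
    name: str
    statistic: float
    passed: bool | None  # None when not evaluable (zero variance)
    detail: str = ""


@dataclass
class SimmenReport:
    """Result of the four 5-methylcytosine-mutation criteria."""

    criteria: list[Criterion]
    table: pd.DataFrame = field(repr=False)

    @property
    def all_pass(self) -> bool:
        return all(c.passed for c in self.criteria)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"criterion": c.name, "statistic": c.statistic, "passed": c.passed,
             "detail": c.detail}
            for c in self.criteria
        )


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float | None:
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def simmen_criteria(
    fragments: Sequence[Fragment | str],
    method: str = "pearson",
    level_margin: float = LEVEL_MARGIN,
) -> SimmenReport:
    """Evaluate the four criteria for 5-methylcytosine mutational pressure.

    "Local" quantities are computed per fragment; at least 30 fragments are
    required for the correlation criteria.  Genome-level deficit/excess flags
    use a small margin around 1 (default 2%) so that a bias-free genome's
    sampling noise does not assert either direction; correlation flags use
    the sign of r.  The r values are reported so users can apply their own
    significance tests downstream.
    """
    fragments = list(fragments)
    if len(fragments) < 30:
        raise ValueError(
            f"need at least 30 fragments for the correlation criteria, got {len(fragments)}"
        )
    cg = normalized_level(fragments, {"CG"})
    tg = normalized_level(fragments, {"TG"})
    ca = normalized_level(fragments, {"CA"})
    table = fragment_oe_table(fragments).dropna()

    r_gc = _corr(table["CG_oe"].to_numpy(), table["gc_fraction"].to_numpy(), method)
    r_tg = _corr(table["CG_oe"].to_numpy(), table["TG_oe"].to_numpy(), method)
    r_ca = _corr(table["CG_oe"].to_numpy(), table["CA_oe"].to_numpy(), method)

    criteria = [
        Criterion(
            "i_genome_cg_suppression",
            cg,
            cg < 1 - level_margin,
            "pooled CG observed/expected below 1",
        ),
        Criterion(
            "ii_tg_ca_excess",
            min(tg, ca),
            tg > 1 + level_margin and ca > 1 + level_margin,
            f"TG o/e {tg:.3f}, CA o/e {ca:.3f} both above 1",
        ),
        Criterion(
            "iii_cg_vs_gc_positive",
            np.nan if r_gc is None else r_gc,
            None if r_gc is None else r_gc > 0,
            "r(local CG o/e, local G+C%)",
        ),
        Criterion(
            "iv_cg_vs_tg_ca_negative",
            np.nan if r_tg is None or r_ca is None else max(r_tg, r_ca),
            None if r_tg is None or r_ca is None else (r_tg < 0 and r_ca < 0),
            "r(local CG o/e, local TG o/e) and r(local CG o/e, local CA o/e)",
        ),
    ]
    return SimmenReport(criteria=criteria, table=table)


@dataclass
class SignatureReport:
    """Genome-level normalized levels and dinucleotide ratios."""

    species_label: str
    sequence_class: str  # all | unique | repeat | inside_islands | outside_islands
    levels: dict[str, float]
    ratios: dict[str, float]
    n_bp: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"species": self.species_label, "sequence_class": self.sequence_class,
             "statistic": name, "value": value}
            for name, value in {**self.levels, **self.ratios}.items()
        ]
        return pd.DataFrame(rows)


#: the oligonucleotide sets reported genome-wide, keyed by display label
STANDARD_SETS: dict[str, tuple[str, ...]] = {
    "CG": ("CG",),
    "CC+GG": ("CC", "GG"),
    "CCC+GGG": ("CCC", "GGG"),
    "CCCC+GGGG": ("CCCC", "GGGG"),
}

STANDARD_RATIOS: dict[str, tuple[str, str]] = {
    "CG/GC": ("CG", "GC"),
    "CA/AC": ("CA", "AC"),
    "TG/GT": ("TG", "GT"),
}


def signature_report(
    fragments: Sequence[Fragment | str],
    species_label: str,
    sequence_class: str = "all",
) -> SignatureReport:
    """Compute the standard level/ratio panel for one fragment set."""
    fragments = list(fragments)
    if not fragments:
        raise ValueError("signature_report requires at least one fragment")
    levels = {
        name: normalized_level(fragments, words)
        for name, words in STANDARD_SETS.items()
    }
    ratios = {
        name: dinucleotide_ratio(fragments, num, den)
        for name, (num, den) in STANDARD_RATIOS.items()
    }
    n_bp = sum(
        len(f) if isinstance(f, str) else f.length for f in fragments
    )
    return SignatureReport(
        species_label=species_label,
        sequence_class=sequence_class,
        levels=levels,
        ratios=ratios,
        n_bp=n_bp,
    )
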