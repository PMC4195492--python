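"""Synthetic genomes with controlled signature structure.

Real vertebrate assemblies are multi-gigabase downloads; every analysis stage
in this package is instead exercised on generated genomes whose signature
properties are known by construction:

* a first-order Markov chain calibrated so that the realized G+C% matches a
  target and the realized dinucleotide observed/expected levels match
  requested multipliers (e.g. CG o/e from ~0.13, marsupial-like, to ~0.78,
  lamprey-like) — see :func:`calibrate_chain`;
* optional long-range "isochore" segments that resample the target G+C%
  every 1–5 Mb;
* soft-masked repeat blocks with a distinct (CC/GG-boosted) composition,
  inserted lowercase;
* runs of undetermined bases (N);
* a mechanistic deamination simulator that converts CG to TG/CA at a rate
  modulated by local G+C% (high-G+C DNA melts less and deaminates less),
  producing genomes that satisfy all four 5-methylcytosine criteria.

All generation is seeded and bit-reproducible.

A first-order chain cannot satisfy an arbitrary multiplier set exactly: with
the mononucleotide marginals pinned, perturbing one dinucleotide forces
compensating shifts in the same row and column.  The calibration therefore
targets the *requested* (non-unit) multipliers exactly and lets the
unconstrained dinucleotides absorb the compensation; the realized full o/e
matrix is available from the returned chain for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .seq_io import GenomeSequence

log = logging.getLogger(__name__)

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


class CalibrationError(ValueError):
    """The requested multiplier set admits no consistent stationary chain."""


@dataclass
class IsochoreSpec:
    """Long-range segmental G+C% structure.

    Segment lengths are drawn uniformly from [seg_min, seg_max] bp and each
    segment's target G+C is the preset's target plus a uniform offset in
    ±gc_spread.
    """

    seg_min: int = 1_000_000
    seg_max: int = 5_000_000
    gc_spread: float = 0.05


@dataclass
class SpeciesPreset:
    """Parameters of one synthetic species.

    ``oe_multipliers`` maps dinucleotides to target observed/expected levels
    (1.0 = independence); unlisted dinucleotides default to 1.0 and absorb
    the compensation required for a consistent chain.
    """

    label: str
    target_gc: float = 0.42
    oe_multipliers: dict[str, float] = field(default_factory=dict)
    isochore: IsochoreSpec | None = None
    repeat_fraction: float = 0.0
    repeat_multipliers: dict[str, float] = field(default_factory=lambda: {"CC": 1.3, "GG": 1.3})
    repeat_block_bp: tuple[int, int] = (500, 5_000)
    n_run_rate: float = 0.0
    n_run_bp: tuple[int, int] = (100, 2_000)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.target_gc < 1.0:
            raise ValueError("target_gc must be in (0, 1)")
        for dinuc, m in self.oe_multipliers.items():
            if m <= 0:
                raise ValueError(f"multiplier for {dinuc} must be positive, got {m}")


#: named presets emulating the observed range of vertebrate CG suppression;
#: the CG values span lamprey-like (~0.78, nearly unmethylated) down to
#: marsupial-like (~0.13), with a coelacanth-like preset that also carries
#: the CC/GG over-representation characteristic of that genome, and a
#: bird-like preset with isochore G+C% segmentation.
PRESETS: dict[str, SpeciesPreset] = {
    "coelacanth_like": SpeciesPreset(
        "coelacanth_like", target_gc=0.43,
        oe_multipliers={"CG": 0.31, "CC": 1.15, "GG": 1.15},
        repeat_fraction=0.1, n_run_rate=1e-6,
    ),
    "medaka_like": SpeciesPreset(
        "medaka_like", target_gc=0.405, oe_multipliers={"CG": 0.46},
        repeat_fraction=0.1, n_run_rate=1e-6,
    ),
    "lamprey_like": SpeciesPreset(
        "lamprey_like", target_gc=0.46, oe_multipliers={"CG": 0.78},
        repeat_fraction=0.1, n_run_rate=1e-6,
    ),
    "marsupial_like": SpeciesPreset(
        "marsupial_like", target_gc=0.38, oe_multipliers={"CG": 0.13},
        repeat_fraction=0.1, n_run_rate=1e-6,
    ),
    "isochore_bird_like": SpeciesPreset(
        "isochore_bird_like", target_gc=0.42, oe_multipliers={"CG": 0.25},
        isochore=IsochoreSpec(), repeat_fraction=0.1, n_run_rate=1e-6,
    ),
}


@dataclass
class CalibratedChain:
    """A stationary first-order chain hitting requested G+C and o/e targets."""

    transition: np.ndarray   # (4, 4) row-stochastic
    stationary: np.ndarray   # (4,)
    realized_oe: np.ndarray  # (4, 4)

    @property
    def gc(self) -> float:
        return float(self.stationary[1] + self.stationary[2])


def _stationary(P: np.ndarray) -> np.ndarray:
    a = np.vstack([P.T - np.eye(4), np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    phi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(phi, 1e-12, None) / np.clip(phi, 1e-12, None).sum()


def calibrate_chain(
    target_gc: float,
    oe_multipliers: dict[str, float] | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> CalibratedChain:
    """Fit transition probabilities p(b|a) ∝ π(b)·m(ab) by fixed point.

    Iterates two multiplicative corrections: the parameter vector π is
    adjusted until the chain's stationary mononucleotide frequencies match
    the target (A=T and C=G marginals from ``target_gc``), and the effective
    multipliers of the *requested* dinucleotides are adjusted until their
    realized o/e levels match the request, both to within ``tol``.

    Raises :class:`CalibrationError`, naming the offending multipliers, when
    the iteration does not converge.
    """
    oe_multipliers = oe_multipliers or {}
    pi_target = np.array(
        [(1 - target_gc) / 2, target_gc / 2, target_gc / 2, (1 - target_gc) / 2]
    )
    m_target = np.ones((4, 4))
    requested = np.zeros((4, 4), dtype=bool)
    for dinuc, m in oe_multipliers.items():
        a, b = _IDX[dinuc[0].upper()], _IDX[dinuc[1].upper()]
        m_target[a, b] = m
        requested[a, b] = True

    pi_param = pi_target.copy()
    m_eff = m_target.copy()
    for _ in range(max_iter):
        P = pi_param[None, :] * m_eff
        P /= P.sum(axis=1, keepdims=True)
        phi = _stationary(P)
        realized = P / phi[None, :]
        mono_err = np.abs(phi - pi_target).max()
        oe_err = np.abs(realized[requested] - m_target[requested]).max() if requested.any() else 0.0
        if mono_err < tol and oe_err < tol:
            return CalibratedChain(transition=P, stationary=phi, realized_oe=realized)
        pi_param = pi_param * pi_target / phi
        pi_param /= pi_param.sum()
        m_eff[requested] *= m_target[requested] / realized[requested]
    bad = sorted(oe_multipliers.items())
    raise CalibrationError(
        f"chain calibration did not converge for gc={target_gc}, multipliers={bad}"
    )


@njit(cache=True)
def _sample_states(cum_rows: np.ndarray, cum_init: np.ndarray, u: np.ndarray) -> np.ndarray:  # pragma: no cover - jitted
    n = len(u)
    out = np.empty(n, dtype=np.uint8)
    s = 0
    for c in range(4):
        if u[0] <= cum_init[c]:
            s = c
            break
    out[0] = s
    for i in range(1, n):
        row = cum_rows[s]
        ui = u[i]
        s = 3
        for c in range(3):
            if ui <= row[c]:
                s = c
                break
        out[i] = s
    return out


def _sample_chain(chain: CalibratedChain, n: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(n)
    cum_rows = np.cumsum(chain.transition, axis=1)
    cum_init = np.cumsum(chain.stationary)
    return _sample_states(cum_rows, cum_init, u)


_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_DECODE_LOWER = np.frombuffer(b"acgtn", dtype=np.uint8)


def codes_to_string(codes: np.ndarray, lower_mask: np.ndarray | None = None) -> str:
    out = _DECODE[codes]
    if lower_mask is not None and lower_mask.any():
        out = np.where(lower_mask, _DECODE_LOWER[codes], out)
    return out.tobytes().decode("ascii")


def _insert_blocks(
    n: int,
    fraction_or_rate: float,
    block_range: tuple[int, int],
    rng: np.random.Generator,
    by_rate: bool,
) -> np.ndarray:
    """Boolean mask covering randomly placed blocks.

    With ``by_rate`` the number of blocks is ``rate * n`` (run starts per
    bp); otherwise enough blocks are placed to cover about
    ``fraction_or_rate`` of the sequence.
    """
    mask = np.zeros(n, dtype=bool)
    lo, hi = block_range
    mean_block = (lo + hi) / 2
    if by_rate:
        n_blocks = rng.poisson(fraction_or_rate * n)
    else:
        n_blocks = int(round(fraction_or_rate * n / mean_block))
    for _ in range(n_blocks):
        length = int(rng.integers(lo, hi + 1))
        if length >= n:
            continue
        start = int(rng.integers(0, n - length))
        mask[start : start + length] = True
    return mask


def markov_genome(
    preset: SpeciesPreset,
    length_bp: int,
    seed: int | None = None,
    record_id: str | None = None,
) -> GenomeSequence:
    """Generate one genome record from a calibrated Markov chain.

    Isochore mode resamples the target G+C per 1–5 Mb segment and
    recalibrates the chain for it; repeat blocks are re-sampled from a
    CC/GG-boosted chain and written lowercase; N runs overwrite sequence at
    the preset's rate.  Generation is deterministic given (preset, seed).
    """
    if length_bp < 1:
        raise ValueError("length_bp must be positive")
    if length_bp < 10_000:
        log.warning("markov_genome below 10 kb; composition targets will be noisy")
    seed = seed if seed is not None else (preset.seed if preset.seed is not None else 0)
    rng = np.random.default_rng(seed)

    if preset.isochore is None:
        chain = calibrate_chain(preset.target_gc, preset.oe_multipliers)
        codes = _sample_chain(chain, length_bp, rng)
    else:
        iso = preset.isochore
        parts = []
        produced = 0
        while produced < length_bp:
            seg_len = min(int(rng.integers(iso.seg_min, iso.seg_max + 1)), length_bp - produced)
            gc = float(
                np.clip(
                    preset.target_gc + rng.uniform(-iso.gc_spread, iso.gc_spread),
                    0.05,
                    0.95,
                )
            )
            chain = calibrate_chain(gc, preset.oe_multipliers)
            parts.append(_sample_chain(chain, seg_len, rng))
            produced += seg_len
        codes = np.concatenate(parts)

    repeat_mask = np.zeros(length_bp, dtype=bool)
    if preset.repeat_fraction > 0:
        repeat_mask = _insert_blocks(
            length_bp, preset.repeat_fraction, preset.repeat_block_bp, rng, by_rate=False
        )
        if repeat_mask.any():
            rep_mult = dict(preset.oe_multipliers)
            rep_mult.update(preset.repeat_multipliers)
            rep_chain = calibrate_chain(preset.target_gc, rep_mult)
            rep_codes = _sample_chain(rep_chain, int(repeat_mask.sum()), rng)
            codes = codes.copy()
            codes[repeat_mask] = rep_codes

    if preset.n_run_rate > 0:
        n_mask = _insert_blocks(
            length_bp, preset.n_run_rate, preset.n_run_bp, rng, by_rate=True
        )
        codes = codes.copy()
        codes[n_mask] = 4

    sequence = codes_to_string(codes, repeat_mask)
    return GenomeSequence(
        species_label=preset.label,
        records=[(record_id or f"{preset.label}_chr1", sequence)],
    )


def deamination_genome(
    base: GenomeSequence,
    mutation_rounds: int = 4,
    p: float = 0.4,
    gc_protection: bool = True,
    compensate: bool = True,
    window: int = 1_000,
    protect_lo: float = 0.25,
    protect_hi: float = 0.55,
    seed: int = 0,
) -> tuple[GenomeSequence, dict[str, int]]:
    """Simulate 5-methylcytosine deamination on an existing genome.

    Per round, each CG site mutates with probability ``p * f(local G+C)``.
    With ``gc_protection`` on, f is a steep ramp — f = 1 at or below
    ``protect_lo`` local G+C, 0 at or above ``protect_hi`` — reflecting the
    strong melting-temperature dependence of strand separation: high-G+C DNA
    stays double-stranded and its cytosines are barely exposed to
    deamination.  (The ramp must be steep: the per-fragment CG→TG flux
    relative to baseline TG grows with G+C% because CG sites scale with
    G+C² while TG scales with (1−G+C)·G+C, so a shallow protection gradient
    would be outweighed by that compositional coupling.)  Without
    protection, f = 1.  Local G+C is measured in a centered ``window``-bp
    window.  A mutating CG becomes TG or CA with equal probability
    (deamination on either strand); every CG lost is one TG or CA gained,
    which is the mechanistic source of criteria ii and iv.

    With ``compensate=False`` a mutating CG becomes GG instead (sites
    preceded by T are left untouched, so the substitution can create
    neither TG nor CA) — an ablation control that removes CG while keeping
    the TG and CA channels strictly closed, isolating the role of the
    compensation in the criterion-iv correlations.

    Returns the mutated genome and a log of mutation counts.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    rng = np.random.default_rng(seed)
    counts = {"cg_lost": 0, "tg_gained": 0, "ca_gained": 0, "gg_gained": 0}
    records: list[tuple[str, str]] = []
    from .seq_io import encode, lowercase_mask

    for rec_id, seq in base.records:
        codes = encode(seq).copy()
        lower = lowercase_mask(seq)
        n = len(codes)
        for _ in range(mutation_rounds):
            cg_pos = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
            if len(cg_pos) == 0:
                break
            if gc_protection:
                is_gc = ((codes == 1) | (codes == 2)).astype(np.float64)
                cum = np.concatenate(([0.0], np.cumsum(is_gc)))
                lo = np.clip(cg_pos - window // 2, 0, n)
                hi = np.clip(cg_pos + window // 2, 0, n)
                local_gc = (cum[hi] - cum[lo]) / np.maximum(hi - lo, 1)
                exposure = (protect_hi - local_gc) / (protect_hi - protect_lo)
                rate = p * np.clip(exposure, 0.0, 1.0)
            else:
                rate = np.full(len(cg_pos), p)
            mutate = rng.random(len(cg_pos)) < rate
            sites = cg_pos[mutate]
            if compensate:
                counts["cg_lost"] += len(sites)
                to_tg = rng.random(len(sites)) < 0.5
                codes[sites[to_tg]] = 3        # CG -> TG
                codes[sites[~to_tg] + 1] = 0   # CG -> CA
                counts["tg_gained"] += int(to_tg.sum())
                counts["ca_gained"] += int((~to_tg).sum())
            else:
                # ablation control: CG -> GG, skipping sites preceded by T so
                # the substitution can create neither TG nor CA anywhere
                sites = sites[(sites == 0) | (codes[np.maximum(sites - 1, 0)] != 3)]
                counts["cg_lost"] += len(sites)
                codes[sites] = 2
                counts["gg_gained"] += len(sites)
        records.append((rec_id, codes_to_string(codes, lower)))
    return GenomeSequence(species_label=base.species_label, records=records), counts


def cohort(
    presets: list[SpeciesPreset] | list[str],
    length_bp_each: int,
    master_seed: int = 0,
) -> list[GenomeSequence]:
    """One genome per preset, with distinct child seeds from a master seed.

    Presets may be given by name (looked up in :data:`PRESETS`) or as
    :class:`SpeciesPreset` objects.  Duplicate labels are an error.
    """
    resolved = [PRESETS[p] if isinstance(p, str) else p for p in presets]
    labels = [p.label for p in resolved]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate preset labels: {labels}")
    child_seeds = np.random.SeedSequence(master_seed).generate_state(len(resolved))
    return [
        markov_genome(preset, length_bp_each, seed=int(s & 0x7FFFFFFF))
        for preset, s in zip(resolved, child_seeds)
    ]


def _island_tile() -> str:
    """A 100-bp tile with fixed composition: 58% G+C and 7 CG dinucleotides
    per cyclic period, so every 100-bp window over its repetition passes the
    canonical island thresholds (GC >= 0.5, CG o/e ~0.83) deterministically."""
    filler = "GGCCATAGCATA"  # no CG inside; C3 G3 A4 T2
    tile = ("CG" + filler) * 7 + "GC"
    assert len(tile) == 100 and "CG" not in filler
    return tile


def planted_island_genome(
    seed: int = 0,
    background_bp: int = 10_000,
    insert_bp: int = 300,
    background_gc: float = 0.30,
    background_cg_oe: float = 0.2,
) -> tuple[GenomeSequence, tuple[int, int]]:
    """A CG-suppressed, A+T-rich background with one planted CpG island.

    The insert is a deterministic repetition of a designed 100-bp tile
    (G+C 58%, CG o/e ≈ 0.83), so the island call cannot fragment on window
    sampling noise; the background is a calibrated suppressed chain whose
    windows fail the GC threshold.  The default background G+C of 0.30
    bounds how far boundary windows (mixing insert and background) can drag
    the island call past the insert: a window passes GC >= 0.5 only when
    more than ~70% of it is insert, limiting the overhang to < 30 bp per
    side.  Returns the genome and the insert's (start, end) interval.
    """
    preset = SpeciesPreset(
        "island_fixture", target_gc=background_gc,
        oe_multipliers={"CG": background_cg_oe},
    )
    background = markov_genome(preset, background_bp, seed=seed)
    seq = background.records[0][1]
    tile = _island_tile()
    insert = (tile * (insert_bp // len(tile) + 1))[:insert_bp]
    start = background_bp // 2
    planted = seq[:start] + insert + seq[start:]
    genome = GenomeSequence(
        species_label="island_fixture", records=[("fixture", planted)]
    )
    return genome, (start, start + insert_bp)
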