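"""Per-lattice observed/expected grids: visualizing diagnostic oligonucleotides.

Raw oligonucleotide frequencies track G+C% so strongly that a map colored by
them mostly re-draws the G+C% gradient.  Dividing each lattice point's
observed class frequency by the frequency expected from that lattice point's
own mononucleotide composition removes the first-order G+C% effect, so the
remaining red/blue (over/under-represented) pattern highlights genuine
signature differences — e.g. CG-containing classes that are far more
suppressed in one species' territory than in its neighbors'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blsom import LatticeAssignment, SOMGrid
from .kmer_signature import BASES, DegenerateKeyMap, mono_composition
from .seq_io import Fragment


@dataclass
class OEGrid:
    """Observed/expected ratio of one oligonucleotide class per lattice point.

    ``ratio`` is NaN only where observed or expected vanish; ``from_data``
    is False on lattice points with no assigned fragments, whose values were
    derived from the weight vector instead.
    """

    oligo_class: str
    ratio: np.ndarray        # (W, H)
    n_fragments: np.ndarray  # (W, H) ints
    from_data: np.ndarray    # (W, H) bool

    def as_frame(self) -> pd.DataFrame:
        w, h = self.ratio.shape
        ii, jj = np.meshgrid(np.arange(w), np.arange(h), indexing="ij")
        return pd.DataFrame(
            {
                "i": ii.ravel(),
                "j": jj.ravel(),
                "ratio": self.ratio.ravel(),
                "n_fragments": self.n_fragments.ravel(),
                "from_data": self.from_data.ravel(),
            }
        )


def _class_mono_content(label: str, k: int) -> np.ndarray:
    """Mononucleotide distribution of a class's member words (length-4)."""
    words = label.split("+")
    counts = np.zeros(4)
    for word in words:
        for base in word:
            counts[BASES.index(base)] += 1
    return counts / (k * len(words))


def lattice_mono_composition(
    grid: SOMGrid,
    assignment: LatticeAssignment,
    fragments: list[Fragment],
    key_map: DegenerateKeyMap,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lattice {A,C,G,T} frequencies, shape (W, H, 4).

    Lattice points with assigned fragments use the mean of those fragments'
    mononucleotide frequency vectors.  Empty lattice points fall back to the
    marginal of the weight vector (each class's frequency spread over its
    member words' base content), renormalized, so downstream grids have no
    holes; the returned boolean array flags which points came from data.
    """
    w, h = grid.width, grid.height
    comp = np.zeros((w, h, 4))
    counts = np.zeros((w, h), dtype=np.int64)
    for (i, j), frag in zip(assignment.coords, fragments):
        mono, _ = mono_composition(frag)
        comp[i, j] += [mono[b] for b in BASES]
        counts[i, j] += 1
    from_data = counts > 0
    comp[from_data] /= counts[from_data][:, None]

    content = np.stack(
        [_class_mono_content(label, key_map.k) for label in key_map.keys]
    )  # (n_classes, 4)
    marginal = grid.weights @ content  # (W, H, 4)
    total = marginal.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        marginal = np.where(total > 0, marginal / total, 0.25)
    comp[~from_data] = marginal[~from_data]
    return comp, from_data


def _expected_from_mono(labels: list[str], mono: np.ndarray) -> np.ndarray:
    """Expected class frequency per lattice point from its mono composition.

    ``mono`` has shape (W, H, 4); returns (W, H) summed over member words of
    the product of constituent base frequencies.
    """
    expected = np.zeros(mono.shape[:2])
    for label in labels:
        for word in label.split("+"):
            term = np.ones(mono.shape[:2])
            for base in word:
                term = term * mono[:, :, BASES.index(base)]
            expected += term
    return expected


def oe_grid(
    grid: SOMGrid,
    assignment: LatticeAssignment,
    fragments: list[Fragment],
    signature: pd.DataFrame,
    key_map: DegenerateKeyMap,
    oligo_class: str | list[str],
) -> OEGrid:
    """Observed/expected grid for one oligonucleotide class (or set of classes).

    Observed is the mean class frequency over the fragments assigned to each
    lattice point (weights are smoothed prototypes; occupied points report
    what their data contain).  Expected comes from the lattice point's own
    mononucleotide composition.  Empty lattice points use the weight vector
    for both, and are flagged.
    """
    labels = [oligo_class] if isinstance(oligo_class, str) else list(oligo_class)
    for label in labels:
        if label not in key_map.keys:
            raise KeyError(f"unknown oligonucleotide class {label!r} for this key map")
    w, h = grid.width, grid.height
    freqs = signature[labels].to_numpy().sum(axis=1)
    observed = np.zeros((w, h))
    counts = np.zeros((w, h), dtype=np.int64)
    for (i, j), f in zip(assignment.coords, freqs):
        observed[i, j] += f
        counts[i, j] += 1
    occupied = counts > 0
    observed[occupied] /= counts[occupied]
    label_idx = [key_map.keys.index(l) for l in labels]
    observed[~occupied] = grid.weights[~occupied][:, label_idx].sum(axis=1)

    mono, from_data = lattice_mono_composition(grid, assignment, fragments, key_map)
    expected = _expected_from_mono(labels, mono)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((observed > 0) & (expected > 0), observed / expected, np.nan)
    return OEGrid(
        oligo_class="+".join(labels) if len(labels) > 1 else labels[0],
        ratio=ratio,
        n_fragments=counts,
        from_data=from_data,
    )


def territory_contrast(
    oe: OEGrid,
    assignment: LatticeAssignment,
    species_partition: set[str],
) -> dict[str, float]:
    """Mean O/E ratio inside vs outside a species partition's territory.

    A lattice point belongs to the partition when the majority of its
    fragments come from partition species; means are weighted by fragment
    count.  Returns the two means and their difference (inside - outside).
    """
    if not species_partition:
        raise ValueError("species_partition is empty")
    inside_sum = inside_n = outside_sum = outside_n = 0.0
    for (i, j), cell in assignment.census.items():
        n = sum(cell.values())
        r = oe.ratio[i, j]
        if not np.isfinite(r):
            continue
        in_part = sum(c for s, c in cell.items() if s in species_partition)
        if in_part * 2 > n:
            inside_sum += r * n
            inside_n += n
        else:
            outside_sum += r * n
            outside_n += n
    inside = inside_sum / inside_n if inside_n else float("nan")
    outside = outside_sum / outside_n if outside_n else float("nan")
    return {"inside": inside, "outside": outside, "difference": inside - outside}


def render_oe_png(oe: OEGrid, path: str) -> None:
    """Export a blue-white-red raster of log2(ratio) clipped to [-1, 1].

    The figure scale is qualitative; the numeric grid is the authoritative
    output.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with np.errstate(invalid="ignore", divide="ignore"):
        img = np.clip(np.log2(oe.ratio), -1.0, 1.0)
    fig, ax = plt.subplots(figsize=(6, 6 * oe.ratio.shape[1] / max(oe.ratio.shape[0], 1)))
    im = ax.imshow(img.T, cmap="bwr", vmin=-1, vmax=1, origin="lower")
    ax.set_title(oe.oligo_class)
    fig.colorbar(im, ax=ax, label="log2 observed/expected")
    fig.savefig(path, dpi=120)
    plt.close(fig)
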