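#!/usr/bin/env python
"""Fragment the cohort into 100-kb windows and count DegTri signatures.

Applies the >20%-N filter, then converts each retained fragment into a
32-dimensional degenerate trinucleotide frequency vector.  Writes the
fragment manifest and the signature matrix consumed by 03.
"""

import sys
from pathlib import Path

import pandas as pd

from genomesig import kmer_signature as ks, seq_io

WINDOW_BP = 100_000


def load_fragments():
    manifest = pd.read_csv("results/cohort_manifest.tsv", sep="\t")
    fragments = []
    filtered = {}
    for row in manifest.itertuples():
        genome = seq_io.read_fasta(row.fasta, row.species)
        flog = seq_io.FragmentFilterLog()
        fragments.extend(seq_io.fragment_genome(genome, WINDOW_BP, filter_log=flog))
        filtered[row.species] = flog.n_filtered
    return fragments, filtered


def main() -> None:
    fragments, filtered = load_fragments()
    seq_io.fragment_manifest(fragments).to_csv(
        "results/fragments.tsv", sep="\t", index=False
    )
    key_map = ks.build_key_map(3, degenerate=True)
    signature, fragments = ks.signature_matrix(fragments, key_map)
    signature.to_csv("results/signature_degtri.tsv", sep="\t", index=False)
    print(f"{len(fragments)} fragments of {WINDOW_BP:,} bp "
          f"({sum(filtered.values())} dropped by the N filter: {filtered})")
    print(f"Signature matrix: {signature.shape[0]} x {key_map.n_classes} DegTri classes")
    per_species = signature.groupby("species_label")["gc_fraction"].agg(["count", "mean"])
    print(per_species.round(4).to_string())


if __name__ == "__main__":
    sys.exit(main())
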