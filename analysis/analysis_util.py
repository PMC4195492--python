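"""Shared helpers for the numbered analysis drivers."""

import pandas as pd

from genomesig import seq_io

WINDOW_BP = 100_000


def load_genomes():
    manifest = pd.read_csv("results/cohort_manifest.tsv", sep="\t")
    return [
        seq_io.read_fasta(row.fasta, row.species) for row in manifest.itertuples()
    ]


def rebuild_fragments(window_bp: int = WINDOW_BP):
    """Re-cut the cohort into the same fragments 02 used (deterministic)."""
    fragments = []
    for genome in load_genomes():
        fragments.extend(seq_io.fragment_genome(genome, window_bp))
    return fragments
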