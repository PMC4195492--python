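"""End-to-end orchestration: genomes in, signature tables and maps out.

``run_signature_pipeline`` chains the stages — read soft-masked FASTA,
fragment, count degenerate oligonucleotide vectors, train a BLSOM, assign and
score species territories, draw observed/expected grids, compute genome-level
CG statistics and the deamination criteria, and detect CpG islands — writing
every intermediate as TSV (plus BED for islands) into a run directory, with a
machine-readable JSON summary.  All randomness flows from one master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blsom, composition_stats, cpg_islands, diagnostics, kmer_signature, seq_io

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    species: list[tuple[str, str]]          # (label, fasta path)
    out_dir: str
    window_bp: int = 100_000
    k: int = 3
    degenerate: bool = True
    sequence_class: str = "all"             # all | unique | repeat
    occupancy_target: float = 10.0
    epochs: int = 100
    r0: float | None = None
    oe_classes: list[str] = field(default_factory=list)
    grouping: dict[str, str] = field(default_factory=dict)
    detect_cpg_islands: bool = True
    max_n_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate species labels: {labels}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        raw["species"] = [tuple(item) for item in raw["species"]]
        config = cls(**raw)
        for label, fasta in config.species:
            if not Path(fasta).exists():
                raise FileNotFoundError(f"{label}: FASTA not found at {fasta}")
        return config


def _stage(name: str):
    log.info("stage: %s", name)


def run_signature_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the run directory.

    Any stage failure aborts with the stage name; artifacts written by
    earlier stages remain in the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {**config.__dict__, "species": list(map(list, config.species))}}
    stage = "load"
    try:
        _stage(stage)
        genomes = [seq_io.read_fasta(path, label) for label, path in config.species]
        if config.sequence_class in ("unique", "repeat"):
            part = 0 if config.sequence_class == "unique" else 1
            genomes = [seq_io.split_by_case(g)[part] for g in genomes]

        stage = "fragment"
        _stage(stage)
        fragments: list[seq_io.Fragment] = []
        filter_counts = {}
        for genome in genomes:
            flog = seq_io.FragmentFilterLog()
            fragments.extend(
                seq_io.fragment_genome(
                    genome, config.window_bp, config.max_n_fraction, filter_log=flog
                )
            )
            filter_counts[genome.species_label] = flog.n_filtered
        summary["n_filtered_fragments"] = filter_counts
        seq_io.fragment_manifest(fragments).to_csv(
            out / "fragments.tsv", sep="\t", index=False
        )

        stage = "signature"
        _stage(stage)
        key_map = kmer_signature.build_key_map(config.k, config.degenerate)
        signature, fragments = kmer_signature.signature_matrix(fragments, key_map)
        signature.to_csv(out / "signature.tsv", sep="\t", index=False)
        vectors = signature[list(key_map.keys)].to_numpy()
        labels = signature["species_label"].tolist()

        stage = "train"
        _stage(stage)
        grid = blsom.pca_initialize(vectors, config.occupancy_target)
        grid = blsom.batch_train(grid, vectors, epochs=config.epochs, r0=config.r0)
        weights = pd.DataFrame(grid.flat_weights(), columns=list(key_map.keys))
        weights.insert(0, "j", np.arange(grid.n_lattice) % grid.height)
        weights.insert(0, "i", np.arange(grid.n_lattice) // grid.height)
        weights.to_csv(out / "weights.tsv", sep="\t", index=False)

        stage = "assign"
        _stage(stage)
        assignment = blsom.assign(grid, vectors, labels)
        pd.DataFrame(
            {
                "fragment": signature.index,
                "species": labels,
                "i": assignment.coords[:, 0],
                "j": assignment.coords[:, 1],
            }
        ).to_csv(out / "assignment.tsv", sep="\t", index=False)
        census_rows = [
            {"i": i, "j": j, "species": s, "count": c}
            for (i, j), cell in sorted(assignment.census.items())
            for s, c in sorted(cell.items())
        ]
        pd.DataFrame(census_rows).to_csv(out / "census.tsv", sep="\t", index=False)
        summary["purity"] = blsom.purity(assignment)
        if config.grouping:
            summary["purity_grouped"] = blsom.purity(assignment, config.grouping)
        summary["map_size"] = [grid.width, grid.height]

        stage = "oe_grids"
        _stage(stage)
        for oligo_class in config.oe_classes:
            oe = diagnostics.oe_grid(
                grid, assignment, fragments, signature, key_map, oligo_class
            )
            safe = oligo_class.replace("+", "_")
            oe.as_frame().to_csv(out / f"oe_{safe}.tsv", sep="\t", index=False)

        stage = "composition"
        _stage(stage)
        by_species: dict[str, list[seq_io.Fragment]] = {}
        for frag in fragments:
            by_species.setdefault(frag.species_label, []).append(frag)
        report_frames = []
        summary["cg_levels"] = {}
        summary["simmen"] = {}
        for label, frags in by_species.items():
            report = composition_stats.signature_report(
                frags, label, config.sequence_class
            )
            report_frames.append(report.as_frame())
            summary["cg_levels"][label] = report.levels["CG"]
            if len(frags) >= 30:
                simmen = composition_stats.simmen_criteria(frags)
                summary["simmen"][label] = {
                    c.name: {"statistic": c.statistic, "passed": c.passed}
                    for c in simmen.criteria
                }
        pd.concat(report_frames, ignore_index=True).to_csv(
            out / "signature_report.tsv", sep="\t", index=False
        )

        if config.detect_cpg_islands:
            stage = "cpg_islands"
            _stage(stage)
            contrast_rows = []
            with open(out / "islands.bed", "w") as bed:
                for genome in genomes:
                    islands = cpg_islands.detect_islands_genome(genome)
                    for seq_id, a, b in islands.intervals:
                        bed.write(f"{genome.species_label}.{seq_id}\t{a}\t{b}\tCpG_island\n")
                    row = {"species": genome.species_label, "n_islands": len(islands)}
                    try:
                        inside, outside = cpg_islands.island_contrast(genome, islands)
                        row["cg_inside"] = inside
                        row["cg_outside"] = outside
                    except composition_stats.UndefinedLevelError:
                        pass
                    contrast_rows.append(row)
            pd.DataFrame(contrast_rows).to_csv(
                out / "island_contrast.tsv", sep="\t", index=False
            )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    summary["seed"] = config.seed
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    return out
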