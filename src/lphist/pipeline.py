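"""End-to-end orchestration: FASTA -> weights -> images -> histograms ->
distance matrices -> UPGMA trees -> optional Robinson-Foulds evaluation.

The default configuration reproduces the reference setup: assignment
scheme "ATGC", self-information weighting from a second-order Markov model
pooled over all input sequences, pixel size 1, 10x10 blocks, 3x3 windows,
all five distance measures.  Every run writes its intermediates plus a
manifest recording the configuration and package version, and is
deterministic given inputs and configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from lphist._version import __version__
from lphist.sequence_io import Sequence, read_fasta
from lphist.markov_model import (
    TrinucleotideModel,
    read_weight_table,
    write_counts_table,
    write_weight_table,
)
from lphist.trajectory import assignment_vectors, build_trajectory
from lphist.binary_image import rasterize, write_image
from lphist.pattern_histogram import (
    PatternHistogram,
    count_patterns,
    normalize,
    write_histogram_tsv,
)
from lphist.distances import (
    MEASURES,
    DistanceMatrix,
    distance_matrix,
    write_matrix_tsv,
    write_phylip,
)
from lphist.phylogeny import from_newick, robinson_foulds, to_newick, upgma

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable knobs of the pipeline; defaults match the reference setup."""

    scheme: str = "ATGC"
    weighting: bool = True
    pixel_size: float = 1.0
    block_size: int = 10
    window: int = 3  # fixed: serial numbers are defined for 3x3 windows
    measures: tuple[str, ...] = MEASURES
    seed: int = 0
    weight_table: str | None = None  # precomputed weights (TSV), overrides corpus
    write_images: bool = False

    def __post_init__(self) -> None:
        if self.window != 3:
            raise ValueError("window size is fixed at 3")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")


def sequence_histogram(
    seq: Sequence,
    config: PipelineConfig,
    weights: list[float] | None,
) -> PatternHistogram:
    """Draw, rasterize, and count one sequence under ``config``."""
    scheme = assignment_vectors(config.scheme)
    traj = build_trajectory(seq, scheme, weights)
    image = rasterize(traj, pixel_size=config.pixel_size, block_size=config.block_size)
    return normalize(count_patterns(image))


def _sequence_weights(
    seqs: list[Sequence], config: PipelineConfig
) -> tuple[TrinucleotideModel | None, dict[str, list[float] | None]]:
    from lphist.markov_model import weight_sequence

    if not config.weighting:
        return None, {s.id: None for s in seqs}
    if config.weight_table:
        model = TrinucleotideModel.from_sequences(seqs)  # counts for the manifest
        table = read_weight_table(config.weight_table)
        model.weights = table
    else:
        model = TrinucleotideModel.from_sequences(seqs)
    return model, {s.id: weight_sequence(s, model) for s in seqs}


def run_pipeline(
    fasta: str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path = "lphist_out",
    reference_tree: str | Path | None = None,
) -> dict:
    """Run the full pipeline on a multi-FASTA file.

    Writes weight and count tables, one histogram TSV per sequence, a
    distance matrix (PHYLIP + TSV) and a UPGMA Newick tree per measure,
    optionally PBM images and Robinson-Foulds distances against a
    reference Newick tree, plus ``manifest.json``.  Returns the in-memory
    results keyed by stage.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    seqs = read_fasta(fasta)
    if len(seqs) < 2:
        raise ValueError("pipeline: need at least 2 sequences")
    logger.info("stage read: %d sequences", len(seqs))

    model, weights = _sequence_weights(seqs, config)
    if model is not None:
        write_weight_table(model, outdir / "weights.tsv")
        write_counts_table(model.counts, outdir / "trinucleotide_counts.tsv")
    logger.info("stage weights done (%.2fs)", time.perf_counter() - t0)

    hists: dict[str, PatternHistogram] = {}
    for seq in seqs:
        if config.write_images:
            scheme = assignment_vectors(config.scheme)
            traj = build_trajectory(seq, scheme, weights[seq.id])
            image = rasterize(traj, config.pixel_size, config.block_size)
            write_image(image, outdir / f"image_{seq.id}.pbm", "PBM")
            hists[seq.id] = normalize(count_patterns(image))
        else:
            hists[seq.id] = sequence_histogram(seq, config, weights[seq.id])
        write_histogram_tsv(hists[seq.id], outdir / f"hist_{seq.id}.tsv")
    logger.info("stage histograms done (%.2fs)", time.perf_counter() - t0)

    matrices: dict[str, DistanceMatrix] = {}
    trees: dict[str, str] = {}
    for measure in config.measures:
        m = distance_matrix(hists, measure)
        matrices[measure] = m
        write_phylip(m, outdir / f"dist_{measure}.phylip")
        write_matrix_tsv(m, outdir / f"dist_{measure}.tsv")
        newick = to_newick(upgma(m))
        trees[measure] = newick
        (outdir / f"tree_{measure}.nwk").write_text(newick + "\n")
    logger.info("stage distances/trees done (%.2fs)", time.perf_counter() - t0)

    rf: dict[str, int] | None = None
    if reference_tree is not None:
        ref = from_newick(Path(reference_tree).read_text())
        rf = {
            measure: robinson_foulds(from_newick(trees[measure]), ref)
            for measure in config.measures
        }
        with open(outdir / "rf.tsv", "w") as fh:
            fh.write("measure\trf\n")
            for measure, value in rf.items():
                fh.write(f"{measure}\t{value}\n")

    manifest = {
        "package": "lphist",
        "version": __version__,
        "config": asdict(config),
        "n_sequences": len(seqs),
        "sequence_ids": [s.id for s in seqs],
        "reference_tree": str(reference_tree) if reference_tree else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "sequences": seqs,
        "model": model,
        "histograms": hists,
        "matrices": matrices,
        "trees": trees,
        "rf": rf,
    }
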