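"""Second-order Markov model of trinucleotides and self-information weights.

Trinucleotide counts are pooled over all input sequences with a sliding
window of length three (one nucleotide per move).  The conditional
probability that base ``z`` follows the doublet ``xy`` is the plain ratio

    P(z | xy) = N_xyz / sum_s N_xys

with no pseudocounts.  The weighting factor attached to a base is its
self-information I = -log2 P in bits, so rare trinucleotides stretch the
trajectory and common ones compress it.  The first two bases of a sequence
have no preceding doublet and get weight 1; the same fallback applies when
a doublet never occurs in the corpus (P undefined) or when the observed
base has probability 0 under a foreign corpus.

Weights are kept at full floating precision; two-significant-figure
display is formatting only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from lphist.sequence_io import ALPHABET, Sequence

logger = logging.getLogger(__name__)

TRIPLETS: tuple[str, ...] = tuple(
    "".join(t) for t in itertools.product(ALPHABET, repeat=3)
)
DOUBLETS: tuple[str, ...] = tuple(
    "".join(d) for d in itertools.product(ALPHABET, repeat=2)
)


def count_trinucleotides(seqs: Iterable[Sequence]) -> dict[str, int]:
    """Count every length-3 window over all sequences, pooled.

    Returns a complete 64-entry map (zeros included).  A sequence of
    length L contributes max(L - 2, 0) windows.
    """
    counts = dict.fromkeys(TRIPLETS, 0)
    for seq in seqs:
        r = seq.residues
        for k in range(len(r) - 2):
            counts[r[k : k + 3]] += 1
    return counts


def conditional_probability(
    counts: Mapping[str, int], x: str, y: str, z: str
) -> float | None:
    """P(z | xy) = N_xyz / sum_s N_xys; ``None`` when the doublet is unseen."""
    denom = sum(counts[x + y + s] for s in ALPHABET)
    if denom == 0:
        return None
    return counts[x + y + z] / denom


def self_information(p: float) -> float:
    """Information content -log2(p) in bits, for p in (0, 1]."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {p!r}")
    return -math.log2(p)


@dataclass
class TrinucleotideModel:
    """Trinucleotide counts, conditional probabilities, and weights.

    ``probabilities[xyz]`` is ``None`` when the doublet ``xy`` never occurs;
    ``weights[xyz]`` is ``None`` when the probability is undefined or zero
    (consumers fall back to weight 1).
    """

    counts: dict[str, int]
    probabilities: dict[str, float | None] = field(init=False)
    weights: dict[str, float | None] = field(init=False)

    def __post_init__(self) -> None:
        missing = set(TRIPLETS) - set(self.counts)
        if missing:
            raise ValueError(f"counts map missing triplets: {sorted(missing)[:4]}...")
        self.probabilities = {}
        self.weights = {}
        for t in TRIPLETS:
            p = conditional_probability(self.counts, t[0], t[1], t[2])
            self.probabilities[t] = p
            self.weights[t] = self_information(p) if p else None

    @classmethod
    def from_sequences(cls, seqs: Iterable[Sequence]) -> "TrinucleotideModel":
        """Build the model by pooling trinucleotide counts over ``seqs``."""
        return cls(counts=count_trinucleotides(seqs))

    @property
    def total_windows(self) -> int:
        return sum(self.counts.values())


def weight_sequence(seq: Sequence, model: TrinucleotideModel) -> list[float]:
    """Per-position weights w_k for drawing the trajectory of ``seq``.

    Positions 1 and 2 get weight 1 (no preceding doublet); position k >= 3
    gets the self-information of P(s_k | s_{k-2} s_{k-1}).  Undefined or
    zero-probability contexts fall back to weight 1 with a log message.
    """
    r = seq.residues
    weights = [1.0] * min(len(r), 2)
    fallbacks = 0
    for k in range(2, len(r)):
        w = model.weights[r[k - 2 : k + 1]]
        if w is None:
            fallbacks += 1
            w = 1.0
        weights.append(w)
    if fallbacks:
        logger.info(
            "sequence %s: %d positions used fallback weight 1 (unseen context)",
            seq.id,
            fallbacks,
        )
    return weights


def bootstrap_weights(
    seqs: list[Sequence],
    subset_size: int,
    trials: int,
    seed: int | np.random.Generator = 0,
) -> dict[str, tuple[float, float]]:
    """Resampling check of weight robustness.

    Each trial draws ``subset_size`` sequences without replacement, rebuilds
    the model, and records all 64 weights (fallback 1 where a doublet is
    unseen in the subset, matching :func:`weight_sequence`).  Returns
    ``{triplet: (mean, population SD)}`` over trials; deterministic for a
    given integer seed.
    """
    if subset_size > len(seqs):
        raise ValueError(
            f"subset_size {subset_size} exceeds number of sequences {len(seqs)}"
        )
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = np.empty((trials, len(TRIPLETS)))
    for trial in range(trials):
        idx = rng.choice(len(seqs), size=subset_size, replace=False)
        model = TrinucleotideModel.from_sequences([seqs[i] for i in idx])
        samples[trial] = [
            model.weights[t] if model.weights[t] is not None else 1.0
            for t in TRIPLETS
        ]
    means = samples.mean(axis=0)
    sds = samples.std(axis=0)  # ddof=0: a single trial has SD 0
    return {t: (means[i], sds[i]) for i, t in enumerate(TRIPLETS)}


def write_weight_table(model: TrinucleotideModel, path: str | Path) -> None:
    """Export weights as TSV in the 4x(4x4) layout: one row per (first,
    third) base pair, columns = second base.  Undefined weights print as NA.
    """
    with open(path, "w") as fh:
        fh.write("first\tthird\t" + "\t".join(ALPHABET) + "\n")
        for x in ALPHABET:
            for z in ALPHABET:
                cells = []
                for y in ALPHABET:
                    w = model.weights[x + y + z]
                    cells.append("NA" if w is None else f"{w:.6f}")
                fh.write(f"{x}\t{z}\t" + "\t".join(cells) + "\n")


def read_weight_table(path: str | Path) -> dict[str, float | None]:
    """Read a weight table written by :func:`write_weight_table`."""
    weights: dict[str, float | None] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        seconds = header[2:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            x, z = parts[0], parts[1]
            for y, cell in zip(seconds, parts[2:]):
                weights[x + y + z] = None if cell == "NA" else float(cell)
    missing = set(TRIPLETS) - set(weights)
    if missing:
        raise ValueError(f"weight table missing triplets: {sorted(missing)[:4]}...")
    return weights


def write_counts_table(counts: Mapping[str, int], path: str | Path) -> None:
    """Export trinucleotide counts as a two-column TSV (triplet, count)."""
    with open(path, "w") as fh:
        fh.write("triplet\tcount\n")
        for t in TRIPLETS:
            fh.write(f"{t}\t{counts[t]}\n")
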