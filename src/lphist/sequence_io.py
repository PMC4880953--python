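"""FASTA input/output, sequence cleaning, and synthetic sequence generation.

Sequences are plain strings over {A, C, G, T}.  Ambiguity codes (N, IUPAC
degenerates) and gap characters are removed rather than randomly resolved,
because the trajectory construction defines a vector for each of the four
canonical bases only; the number of removed characters is reported so that
heavily degenerate inputs are visible to the caller.

Mitochondrial genomes are circular, but sequences are treated as linear
here: the trajectory has a distinct origin and terminus.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class Sequence:
    """An identified DNA string over {A, C, G, T}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGT characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def clean_sequence(raw: str) -> tuple[str, int]:
    """Remove all characters outside {A,C,G,T} (case-insensitive).

    Returns the cleaned, upper-cased string and the number of characters
    removed.  An empty result is allowed.
    """
    upper = raw.upper()
    kept = [c for c in upper if c in _BASE_INDEX]
    removed = len(upper) - len(kept)
    if removed:
        logger.info("removed %d non-ACGT characters", removed)
    return "".join(kept), removed


def read_fasta(path: str | Path, clean: bool = True) -> list[Sequence]:
    """Read a (multi-)FASTA file into a list of :class:`Sequence`.

    Record order is preserved and residues are upper-cased.  With
    ``clean=True`` (default) non-ACGT characters are dropped with a logged
    count.  Duplicate record ids raise ``ValueError``; malformed input
    raises ``ValueError`` naming the offending line.
    """
    path = Path(path)
    seqs: list[Sequence] = []
    seen: set[str] = set()
    with open(path) as handle:
        # reject leading junk before the first header with a line number
        for lineno, line in enumerate(handle, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
                )
            break
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
            seen.add(record.id)
            residues = str(record.seq).upper()
            if clean:
                residues, removed = clean_sequence(residues)
                if removed:
                    logger.info(
                        "sequence %s: removed %d non-ACGT characters",
                        record.id,
                        removed,
                    )
            seqs.append(Sequence(id=record.id, residues=residues))
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as FASTA, wrapping lines at ``width`` characters."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def _validate_transition_table(
    table: Mapping[str, TypingSequence[float]], tol: float = 1e-6
) -> dict[str, np.ndarray]:
    """Check an order-2 transition table {xy -> probs over ACGT}."""
    validated: dict[str, np.ndarray] = {}
    for x in ALPHABET:
        for y in ALPHABET:
            key = x + y
            if key not in table:
                raise ValueError(f"transition table missing doublet {key!r}")
            row = np.asarray(table[key], dtype=float)
            if row.shape != (4,) or np.any(row < 0):
                raise ValueError(f"transition row {key!r} is not 4 non-negative probabilities")
            if abs(row.sum() - 1.0) > tol:
                raise ValueError(
                    f"transition row {key!r} sums to {row.sum():.6f}, expected 1"
                )
            validated[key] = row / row.sum()
    return validated


def generate_random_sequence(
    length: int,
    model: str | Mapping[str, TypingSequence[float]] = "iid",
    seed: int | np.random.Generator = 0,
    id: str = "synthetic",
) -> Sequence:
    """Generate a random DNA sequence, reproducible for a given seed.

    Parameters
    ----------
    length : int
        Number of bases, >= 1.
    model : "iid" or mapping
        ``"iid"`` draws each base uniformly.  A mapping ``{"AA": [pA, pC,
        pG, pT], ...}`` (all 16 doublets) draws the first two bases
        uniformly and each subsequent base from ``P(z | previous doublet)``.
    seed : int or numpy Generator
        Source of randomness; the same integer seed always yields the same
        sequence.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model == "iid":
        idx = rng.integers(0, 4, size=length)
        return Sequence(id=id, residues="".join(ALPHABET[i] for i in idx))
    table = _validate_transition_table(model)
    first = rng.integers(0, 4, size=min(length, 2))
    bases = [ALPHABET[i] for i in first]
    for _ in range(length - 2):
        row = table[bases[-2] + bases[-1]]
        bases.append(ALPHABET[rng.choice(4, p=row)])
    return Sequence(id=id, residues="".join(bases))
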