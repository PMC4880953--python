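"""2D graphical representation of DNA sequences.

Each base maps to one of the four diagonal unit-square vectors (1,1),
(-1,1), (-1,-1), (1,-1); a sequence is drawn by cumulatively summing its
base vectors, each optionally scaled by a per-position weight:

    R_i = sum_{k=1..i} w_k * V_k,   R_0 = (0, 0).

Up to the symmetries of the plane (90-degree rotations and axis
reflections) there are exactly three distinct ways to assign the four
vectors to A, T, G, C; they are labelled by the counterclockwise base
order starting from the (+,+) quadrant.  The default "ATGC" puts A and T
in the upper half-plane and G and C in the lower one, so the final
y-coordinate of an unweighted trajectory reads out (#A + #T) - (#G + #C),
i.e. the AT/GC composition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence as TypingSequence

import numpy as np

from lphist.sequence_io import Sequence

# diagonal unit-square vectors in counterclockwise order from the (+,+) quadrant
_DIAGONALS: tuple[tuple[int, int], ...] = ((1, 1), (-1, 1), (-1, -1), (1, -1))

SCHEME_LABELS = ("ATGC", "ATCG", "AGTC")


@dataclass(frozen=True)
class AssignmentScheme:
    """A bijection from bases to the four diagonal vectors."""

    label: str
    vectors: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        vecs = sorted(self.vectors.values())
        if sorted(_DIAGONALS) != vecs:
            raise ValueError("vectors must be the four diagonals, each used once")


def assignment_vectors(label: str = "ATGC") -> AssignmentScheme:
    """The base-to-vector assignment named by counterclockwise base order.

    ``label[k]`` is the base placed on the k-th diagonal counterclockwise
    from (1, 1).  Only the three canonical labels are accepted; every other
    bijection is equivalent to one of them under rotation/reflection.
    """
    if label not in SCHEME_LABELS:
        raise ValueError(f"unknown assignment scheme {label!r}; choose from {SCHEME_LABELS}")
    return AssignmentScheme(
        label=label, vectors=dict(zip(label, _DIAGONALS))
    )


def _symmetry_group() -> list[np.ndarray]:
    """The order-8 group generated by 90-degree rotation and x-axis reflection."""
    rot = np.array([[0, -1], [1, 0]])
    ref = np.array([[1, 0], [0, -1]])
    group: list[np.ndarray] = [np.eye(2, dtype=int)]
    frontier = [np.eye(2, dtype=int)]
    while frontier:
        m = frontier.pop()
        for g in (rot, ref):
            cand = g @ m
            if not any(np.array_equal(cand, h) for h in group):
                group.append(cand)
                frontier.append(cand)
    return group


def enumerate_assignment_classes() -> int:
    """Count equivalence classes of base-to-diagonal assignments.

    Enumerates all 4! = 24 bijections from {A,T,G,C} to the diagonal
    vectors and groups them into orbits under the order-8 symmetry group of
    90-degree rotations and axis reflections.
    """
    group = _symmetry_group()
    bases = "ATGC"
    orbits: set[frozenset] = set()
    for perm in itertools.permutations(_DIAGONALS):
        assignment = dict(zip(bases, perm))
        orbit = frozenset(
            tuple(tuple(int(c) for c in g @ np.array(assignment[b])) for b in bases)
            for g in group
        )
        orbits.add(orbit)
    return len(orbits)


@dataclass(frozen=True)
class Trajectory:
    """Cumulative points R_0 .. R_L of a drawn sequence.

    ``points`` has shape (L + 1, 2); ``points[0]`` is the origin.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("points must be an (n >= 1, 2) array")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def segments(self) -> np.ndarray:
        """Array of shape (L, 2, 2): consecutive point pairs."""
        return np.stack([self.points[:-1], self.points[1:]], axis=1)


def build_trajectory(
    seq: Sequence,
    scheme: AssignmentScheme | None = None,
    weights: TypingSequence[float] | None = None,
) -> Trajectory:
    """Accumulate the (optionally weighted) trajectory of a sequence.

    ``weights`` must have one entry per base, or be None for the unweighted
    drawing (all weights 1).
    """
    if scheme is None:
        scheme = assignment_vectors("ATGC")
    n = len(seq.residues)
    if weights is not None and len(weights) != n:
        raise ValueError(
            f"weights length {len(weights)} != sequence length {n}"
        )
    steps = np.array(
        [scheme.vectors[b] for b in seq.residues], dtype=float
    ).reshape(n, 2)
    if weights is not None:
        steps *= np.asarray(weights, dtype=float)[:, None]
    points = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return Trajectory(points=points)


def write_trajectory_tsv(traj: Trajectory, path: str | Path) -> None:
    """Export points as TSV of (index, x, y), for external plotting."""
    with open(path, "w") as fh:
        fh.write("i\tx\ty\n")
        for i, (x, y) in enumerate(traj.points):
            fh.write(f"{i}\t{x:.10g}\t{y:.10g}\n")
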