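"""Five distance measures between local-pattern histograms.

All measures operate on frequencies p_i, q_i over serial numbers 1..511
(absent serials count as 0), each histogram normalized to sum 1:

* HI  — histogram intersection, D = 1 - sum min(p_i, q_i); range [0, 1].
* MD  — Manhattan (L1 / city-block), D = sum |p_i - q_i|; range [0, 2].
  For normalized histograms D_HI = D_MD / 2 exactly.
* BD  — Bhattacharyya, D = -ln sum sqrt(p_i q_i); +inf on disjoint supports.
* JS  — Jensen-Shannon divergence with base-2 logarithms; range [0, 1],
  equal to 1 exactly when supports are disjoint.
* TAU — Kendall rank correlation (tau-b over all serial pairs, with tie
  corrections), converted to a distance as D = (1 - tau) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from lphist.pattern_histogram import N_PATTERNS, PatternHistogram

MEASURES = ("HI", "MD", "BD", "JS", "TAU")


def _freq_vector(hist: PatternHistogram) -> np.ndarray:
    """Dense frequency vector over serials 1..511; requires normalization."""
    if not hist.is_normalized:
        raise ValueError("histogram is not normalized; call normalize() first")
    v = np.zeros(N_PATTERNS)
    for s, f in hist.frequencies.items():
        v[s - 1] = f
    return v


def _pair(P: PatternHistogram, Q: PatternHistogram) -> tuple[np.ndarray, np.ndarray]:
    return _freq_vector(P), _freq_vector(Q)


def hi_distance(P: PatternHistogram, Q: PatternHistogram) -> float:
    """1 - sum min(p_i, q_i): zero iff identical, one iff disjoint supports."""
    p, q = _pair(P, Q)
    return float(1.0 - np.minimum(p, q).sum())


def md_distance(P: PatternHistogram, Q: PatternHistogram) -> float:
    """L1 distance sum |p_i - q_i|."""
    p, q = _pair(P, Q)
    return float(np.abs(p - q).sum())


def bd_distance(P: PatternHistogram, Q: PatternHistogram) -> float:
    """-ln of the Bhattacharyya coefficient sum sqrt(p_i q_i).

    Disjoint supports give a coefficient of 0 and distance +inf; callers
    building matrices treat that as an error rather than clamping.
    """
    p, q = _pair(P, Q)
    div = np.sqrt(p * q).sum()
    if div == 0.0:
        return float("inf")
    # coefficient can exceed 1 by float round-off for identical inputs
    return float(-np.log(min(div, 1.0)))


def js_divergence(P: PatternHistogram, Q: PatternHistogram) -> float:
    """Jensen-Shannon divergence, log base 2 (so the range is [0, 1]).

    Terms with a zero numerator contribute 0; serials absent from both
    histograms are excluded.
    """
    p, q = _pair(P, Q)
    m = p + q
    keep = m > 0
    p, q, m = p[keep], q[keep], m[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        left = np.where(p > 0, p * np.log2(2 * p / m), 0.0)
        right = np.where(q > 0, q * np.log2(2 * q / m), 0.0)
    return float(0.5 * left.sum() + 0.5 * right.sum())


def kendall_tau_stats(p: np.ndarray, q: np.ndarray) -> tuple[int, int, int, int]:
    """Concordant/discordant/tie pair counts (X, Y, r, s) over i > j pairs.

    Pairs tied in both vectors are excluded.  Vectorized over all
    N*(N-1)/2 pairs; the brute-force definition, not an O(N log N) trick.
    """
    dp = np.sign(p[:, None] - p[None, :])
    dq = np.sign(q[:, None] - q[None, :])
    iu = np.triu_indices(len(p), k=1)
    dp, dq = dp[iu], dq[iu]
    X = int(((dp * dq) > 0).sum())
    Y = int(((dp * dq) < 0).sum())
    r = int(((dp == 0) & (dq != 0)).sum())
    s = int(((dp != 0) & (dq == 0)).sum())
    return X, Y, r, s


def kendall_tau_distance(P: PatternHistogram, Q: PatternHistogram) -> float:
    """(1 - tau_b) / 2 with tau_b = (X - Y) / sqrt((X+Y+r)(X+Y+s))."""
    p, q = _pair(P, Q)
    X, Y, r, s = kendall_tau_stats(p, q)
    denom = (X + Y + r) * (X + Y + s)
    if denom == 0:
        raise ValueError("Kendall tau undefined: all serial pairs are tied")
    tau = (X - Y) / np.sqrt(denom)
    return float((1.0 - tau) / 2.0)


_MEASURE_FUNCS = {
    "HI": hi_distance,
    "MD": md_distance,
    "BD": bd_distance,
    "JS": js_divergence,
    "TAU": kendall_tau_distance,
}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("matrix diagonal is not zero")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def distance_matrix(
    hists: Mapping[str, PatternHistogram], measure: str
) -> DistanceMatrix:
    """All pairwise distances between labeled, normalized histograms."""
    if measure not in _MEASURE_FUNCS:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    labels = tuple(hists)
    if len(labels) < 2:
        raise ValueError("need at least 2 histograms")
    func = _MEASURE_FUNCS[measure]
    n = len(labels)
    values = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = func(hists[labels[a]], hists[labels[b]])
            if not np.isfinite(d):
                raise ValueError(
                    f"{measure} distance between {labels[a]!r} and {labels[b]!r} "
                    "is not finite (disjoint supports)"
                )
            values[a, b] = values[b, a] = d
    return DistanceMatrix(labels=labels, values=values, measure=measure)


def matrix_correlation(m1: DistanceMatrix, m2: DistanceMatrix) -> float:
    """Pearson correlation of two distance matrices over the strict upper
    triangle (diagonal zeros and the duplicated lower triangle would bias r).
    """
    if m1.labels != m2.labels:
        raise ValueError("distance matrices have different labels")
    if len(m1.labels) < 3:
        raise ValueError("need at least 3 taxa for a meaningful correlation")
    iu = np.triu_indices(len(m1.labels), k=1)
    x, y = m1.values[iu], m2.values[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant distance matrix")
    return float(stats.pearsonr(x, y).statistic)


def write_phylip(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write the matrix in relaxed PHYLIP square format.

    Labels are width-padded to 10 characters but not truncated (relaxed
    convention), so label round-trips are exact.
    """
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels)}\n")
        for label, row in zip(matrix.labels, matrix.values):
            name = label.ljust(10)
            # 17 significant digits round-trip doubles exactly, so a tree
            # built from the file equals one built from the in-memory matrix
            fh.write(name + "  " + "  ".join(f"{v:.17g}" for v in row) + "\n")


def read_phylip(path: str | Path, measure: str = "NA") -> DistanceMatrix:
    """Read a PHYLIP square distance matrix written by :func:`write_phylip`."""
    with open(path) as fh:
        n = int(fh.readline().strip())
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(labels=tuple(labels), values=np.array(rows), measure=measure)


def write_matrix_tsv(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with a label header row and column."""
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(matrix.labels) + "\n")
        for label, row in zip(matrix.labels, matrix.values):
            fh.write(label + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
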