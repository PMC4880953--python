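"""3x3 local-pattern serial numbers and occurrence-frequency histograms.

A local pattern is the content of a 3x3 pixel window, read row-major from
the upper-left corner with the upper-left pixel as the highest bit, giving
serial numbers 0..511.  Serial 0 (all white) is the empty background and
is never stored in histograms, leaving 511 informative patterns.

Counting slides the window one pixel per move.  The fast path enumerates
only window positions whose 3x3 extent intersects a marked block (each
block expanded by a 2-pixel halo, positions deduplicated), which is
exactly equivalent to a brute-force scan of the full bounding box: every
black pixel lies in a marked block, and windows seeing no black pixel have
serial 0 and are excluded anyway.

Windows are anchored at their top-left pixel.  In trajectory coordinates
(y up) the window anchored at (i, j) covers columns i..i+2 and rows
j, j-1, j-2 from top to bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from lphist.binary_image import BinaryImage

N_PATTERNS = 511  # largest serial; 2^9 - 1, all-white excluded

# bit weight of window cell (row r, col c): upper-left is the highest bit
_BIT_WEIGHTS = np.array([[256, 128, 64], [32, 16, 8], [4, 2, 1]], dtype=np.int64)


def serial_number(window: np.ndarray) -> int:
    """Encode a 3x3 binary window as its serial number in [0, 511]."""
    w = np.asarray(window)
    if w.shape != (3, 3):
        raise ValueError(f"window must be 3x3, got shape {w.shape}")
    if not np.isin(w, (0, 1)).all():
        raise ValueError("window entries must be 0 or 1")
    return int((w * _BIT_WEIGHTS).sum())


@dataclass(frozen=True)
class PatternHistogram:
    """Occurrence counts (and optional normalized frequencies) of local patterns."""

    counts: dict[int, int]
    frequencies: dict[int, float] | None = None
    window: int = 3

    def __post_init__(self) -> None:
        for s, c in self.counts.items():
            if not 1 <= s <= N_PATTERNS:
                raise ValueError(f"serial {s} outside 1..{N_PATTERNS}")
            if c < 0:
                raise ValueError(f"negative count for serial {s}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def is_normalized(self) -> bool:
        return self.frequencies is not None


def normalize(hist: PatternHistogram) -> PatternHistogram:
    """Attach frequencies p_i = count_i / total; idempotent."""
    total = hist.total
    if total == 0:
        raise ValueError("cannot normalize empty histogram")
    freqs = {s: c / total for s, c in hist.counts.items() if c > 0}
    return PatternHistogram(
        counts=dict(hist.counts), frequencies=freqs, window=hist.window
    )


def _window_anchors(image: BinaryImage) -> np.ndarray:
    """Deduplicated anchors of all windows intersecting a marked block.

    The window at anchor (i, j) spans columns i..i+2 and rows j-2..j, so it
    intersects block (bx, by) of size B iff i in [bx*B - 2, bx*B + B - 1]
    and j in [by*B, by*B + B + 1].
    """
    b = image.block_size
    side_i = np.arange(-2, b)
    side_j = np.arange(0, b + 2)
    chunks = []
    for bx, by in image.blocks:
        ii, jj = np.meshgrid(bx * b + side_i, by * b + side_j, indexing="ij")
        chunks.append(np.column_stack([ii.ravel(), jj.ravel()]))
    anchors = np.vstack(chunks)
    return np.unique(anchors, axis=0)


def count_patterns(image: BinaryImage) -> PatternHistogram:
    """Histogram of 3x3 patterns over all window positions of the image.

    Equivalent to sliding the window one pixel per move over the whole
    plane; only windows containing at least one black pixel contribute
    (serial 0 excluded), so enumeration is restricted to marked blocks
    plus a halo.  Empty image yields an empty histogram.
    """
    if not image.black:
        return PatternHistogram(counts={})
    anchors = _window_anchors(image)
    black = np.array(sorted(image.black), dtype=np.int64)
    # encode (i, j) pairs as scalars for fast membership tests; the code
    # range must cover every probed pixel, not just the black ones
    min_i = min(int(black[:, 0].min()), int(anchors[:, 0].min()))
    min_j = min(int(black[:, 1].min()), int(anchors[:, 1].min()) - 2)
    max_j = max(int(black[:, 1].max()), int(anchors[:, 1].max()))
    span_j = max_j - min_j + 1
    black_codes = (black[:, 0] - min_i) * span_j + (black[:, 1] - min_j)
    serials = np.zeros(len(anchors), dtype=np.int64)
    for r in range(3):
        for c in range(3):
            px_i = anchors[:, 0] + c
            px_j = anchors[:, 1] - r
            codes = (px_i - min_i) * span_j + (px_j - min_j)
            hit = np.isin(codes, black_codes)
            serials += hit * int(_BIT_WEIGHTS[r, c])
    serials = serials[serials > 0]
    values, freq = np.unique(serials, return_counts=True)
    return PatternHistogram(counts={int(s): int(n) for s, n in zip(values, freq)})


def write_histogram_tsv(hist: PatternHistogram, path: str | Path) -> None:
    """Export as TSV (serial, count, frequency), serials ascending."""
    with open(path, "w") as fh:
        fh.write("serial\tcount\tfrequency\n")
        total = hist.total
        for s in sorted(hist.counts):
            freq = hist.counts[s] / total if total else 0.0
            fh.write(f"{s}\t{hist.counts[s]}\t{freq:.12g}\n")


def read_histogram_tsv(path: str | Path) -> PatternHistogram:
    """Read a histogram TSV written by :func:`write_histogram_tsv`."""
    counts: dict[int, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("serial"):
            raise ValueError(f"{path}: not a histogram TSV")
        for line in fh:
            parts = line.split("\t")
            counts[int(parts[0])] = int(parts[1])
    hist = PatternHistogram(counts=counts)
    return normalize(hist) if hist.total else hist
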