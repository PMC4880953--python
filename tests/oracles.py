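"""Independent brute-force oracles and random-object builders for tests.

These deliberately avoid the package's fast paths: pattern counts come
from a full bounding-box scan, and rasterization from exhaustive
closed-square/segment intersection tests.
"""

import math

import numpy as np

from lphist.binary_image import BinaryImage
from lphist.pattern_histogram import PatternHistogram, normalize


def random_image(rng, n_pixels=25, span=30, block_size=10):
    """A random sparse binary image for counter tests."""
    pts = rng.integers(-span // 2, span // 2, size=(n_pixels, 2))
    return BinaryImage(
        black=frozenset(map(tuple, pts.tolist())), block_size=block_size
    )


def random_histogram(rng, support=12):
    """A random normalized histogram on a small random support."""
    serials = rng.choice(np.arange(1, 512), size=support, replace=False)
    counts = rng.integers(1, 50, size=support)
    return normalize(
        PatternHistogram(counts={int(s): int(c) for s, c in zip(serials, counts)})
    )


def brute_force_pattern_counts(black):
    """Scan every 3x3 window over the (expanded) bounding box, reading bits
    row-major with the upper-left pixel as the highest bit; drop serial 0.
    """
    black = set(black)
    if not black:
        return {}
    is_ = [p[0] for p in black]
    js = [p[1] for p in black]
    counts = {}
    for ai in range(min(is_) - 2, max(is_) + 1):
        for aj in range(min(js), max(js) + 3):
            serial = 0
            bit = 8
            for r in range(3):
                for c in range(3):
                    if (ai + c, aj - r) in black:
                        serial |= 1 << bit
                    bit -= 1
            if serial:
                counts[serial] = counts.get(serial, 0) + 1
    return counts


def segment_meets_closed_square(x0, y0, x1, y1, i, j):
    """Does the closed segment intersect the closed unit square
    [i, i+1] x [j, j+1]?  Interval clipping with closed bounds.
    """
    lo, hi = 0.0, 1.0
    for a, d, bmin, bmax in ((x0, x1 - x0, i, i + 1), (y0, y1 - y0, j, j + 1)):
        if d == 0.0:
            if not bmin <= a <= bmax:
                return False
        else:
            t1, t2 = (bmin - a) / d, (bmax - a) / d
            lo = max(lo, min(t1, t2))
            hi = min(hi, max(t1, t2))
    return lo <= hi


def oracle_segment_pixels(x0, y0, x1, y1):
    """All pixels meeting the segment, by exhaustive closed-square tests."""
    imin = math.floor(min(x0, x1)) - 1
    imax = math.floor(max(x0, x1)) + 1
    jmin = math.floor(min(y0, y1)) - 1
    jmax = math.floor(max(y0, y1)) + 1
    return {
        (i, j)
        for i in range(imin, imax + 1)
        for j in range(jmin, jmax + 1)
        if segment_meets_closed_square(x0, y0, x1, y1, i, j)
    }
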