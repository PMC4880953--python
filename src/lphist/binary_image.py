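"""Rasterization of trajectories into binary images.

A pixel of side ``s`` at integer index (i, j) covers the closed square
[i*s, (i+1)*s] x [j*s, (j+1)*s].  A pixel is black iff some trajectory
segment intersects that closed square — "at least a portion of a vector" —
so a segment crossing a lattice corner exactly marks all four pixels
meeting there (supercover rasterization with closed-pixel membership).
Boundary contact is resolved by the closed-membership rule itself, not by
epsilon perturbation.

The image also keeps a block index: the plane is divided into
``block_size`` x ``block_size`` pixel squares and a block is marked iff it
contains at least one black pixel.  Pattern counting visits marked blocks
only, which makes the cost proportional to the inked area rather than to
the full bounding box.

Pixel indices may be negative internally; they are shifted to a
non-negative raster only at export.  In the exported raster, row 0 is the
top (largest trajectory y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from lphist.trajectory import Trajectory


def _interval_indices(u: float) -> tuple[int, ...]:
    """Indices i with i <= u <= i+1 (two when u is an exact integer)."""
    f = math.floor(u)
    if u == f:
        return (f - 1, f)
    return (f,)


def _point_pixels(x: float, y: float) -> set[tuple[int, int]]:
    return {
        (i, j) for i in _interval_indices(x) for j in _interval_indices(y)
    }


def _segment_pixels(
    x0: float, y0: float, x1: float, y1: float
) -> set[tuple[int, int]]:
    """All pixels whose closed unit square meets the closed segment."""
    pixels = _point_pixels(x0, y0) | _point_pixels(x1, y1)
    dx, dy = x1 - x0, y1 - y0
    if dx == 0.0 and dy == 0.0:
        return pixels
    # parameter values where the segment crosses an integer grid line,
    # tagged with the axis so the crossing coordinate stays exact
    events: list[tuple[float, int, int]] = []  # (t, axis, gridline k)
    if dx != 0.0:
        lo, hi = sorted((x0, x1))
        for k in range(math.ceil(lo), math.floor(hi) + 1):
            t = (k - x0) / dx
            if 0.0 <= t <= 1.0:
                events.append((t, 0, k))
    if dy != 0.0:
        lo, hi = sorted((y0, y1))
        for k in range(math.ceil(lo), math.floor(hi) + 1):
            t = (k - y0) / dy
            if 0.0 <= t <= 1.0:
                events.append((t, 1, k))
    for t, axis, k in events:
        if axis == 0:
            pixels |= _point_pixels(float(k), y0 + t * dy)
        else:
            pixels |= _point_pixels(x0 + t * dx, float(k))
    # interior of each inter-event span: indices are constant there
    ts = sorted({0.0, 1.0, *(t for t, _, _ in events)})
    for ta, tb in zip(ts[:-1], ts[1:]):
        tm = (ta + tb) / 2.0
        pixels |= _point_pixels(x0 + tm * dx, y0 + tm * dy)
    return pixels


def mark_blocks(
    black: Iterable[tuple[int, int]] | "BinaryImage", block_size: int = 10
) -> frozenset[tuple[int, int]]:
    """Block (bi, bj) is marked iff it contains a black pixel.

    Blocks tile the pixel grid anchored at (0, 0); floor division handles
    negative pixel indices.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if isinstance(black, BinaryImage):
        black = black.black
    return frozenset((i // block_size, j // block_size) for i, j in black)


@dataclass(frozen=True)
class BinaryImage:
    """A set of black pixels with its marked-block index."""

    black: frozenset[tuple[int, int]]
    block_size: int = 10
    blocks: frozenset[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "black", frozenset(self.black))
        object.__setattr__(
            self, "blocks", mark_blocks(self.black, self.block_size)
        )

    @property
    def extents(self) -> tuple[int, int]:
        """(W, H): width and height in pixels of the marked-block bounding box."""
        if not self.blocks:
            return (0, 0)
        bis = [b[0] for b in self.blocks]
        bjs = [b[1] for b in self.blocks]
        w = (max(bis) - min(bis) + 1) * self.block_size
        h = (max(bjs) - min(bjs) + 1) * self.block_size
        return (w, h)

    @property
    def pixel_bounds(self) -> tuple[int, int, int, int]:
        """(min_i, max_i, min_j, max_j) over black pixels."""
        if not self.black:
            raise ValueError("empty image has no bounds")
        is_ = [p[0] for p in self.black]
        js = [p[1] for p in self.black]
        return (min(is_), max(is_), min(js), max(js))


def rasterize(
    traj: Trajectory, pixel_size: float = 1.0, block_size: int = 10
) -> BinaryImage:
    """Supercover-rasterize a trajectory onto the pixel grid.

    With the default ``pixel_size`` of 1, an unweighted step spans exactly
    one pixel diagonal.  A single-point trajectory inks the pixel(s)
    containing that point.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    pts = traj.points / pixel_size
    black: set[tuple[int, int]] = set()
    if len(pts) == 1:
        black |= _point_pixels(pts[0, 0], pts[0, 1])
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        black |= _segment_pixels(x0, y0, x1, y1)
    return BinaryImage(black=frozenset(black), block_size=block_size)


def _raster_array(image: BinaryImage) -> tuple[np.ndarray, int, int]:
    """Dense 0/1 array (rows top to bottom) plus the (min_i, max_j) origin."""
    min_i, max_i, min_j, max_j = image.pixel_bounds
    width = max_i - min_i + 1
    height = max_j - min_j + 1
    arr = np.zeros((height, width), dtype=np.uint8)
    for i, j in image.black:
        arr[max_j - j, i - min_i] = 1  # row 0 = top (largest j)
    return arr, min_i, max_j


def write_image(image: BinaryImage, path: str | Path, format: str = "PBM") -> None:
    """Write the image as plain PBM (bit-exact, 1 = black) or PNG.

    The PBM carries an ``# origin i j`` comment (pixel index of the
    top-left raster cell) so that :func:`read_pbm` restores the exact
    black-pixel coordinates.
    """
    if not image.black:
        raise ValueError("empty image")
    arr, min_i, max_j = _raster_array(image)
    path = Path(path)
    fmt = format.upper()
    if fmt == "PBM":
        with open(path, "w") as fh:
            fh.write("P1\n")
            fh.write(f"# origin {min_i} {max_j}\n")
            fh.write(f"{arr.shape[1]} {arr.shape[0]}\n")
            for row in arr:
                fh.write(" ".join(str(v) for v in row) + "\n")
    elif fmt == "PNG":
        from PIL import Image

        Image.fromarray((1 - arr) * np.uint8(255), mode="L").convert("1").save(path)
    else:
        raise ValueError(f"unknown format {format!r}; use PBM or PNG")


def read_pbm(path: str | Path, block_size: int = 10) -> BinaryImage:
    """Read a plain PBM written by :func:`write_image`."""
    tokens: list[str] = []
    origin_i, origin_j = 0, 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line.split()
                if len(parts) >= 4 and parts[1] == "origin":
                    origin_i, origin_j = int(parts[2]), int(parts[3])
                continue
            tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise ValueError(f"{path}: not a plain PBM (P1) file")
    width, height = int(tokens[1]), int(tokens[2])
    bits = tokens[3:]
    if len(bits) != width * height:
        raise ValueError(f"{path}: expected {width * height} pixels, got {len(bits)}")
    black = set()
    for idx, bit in enumerate(bits):
        if bit == "1":
            row, col = divmod(idx, width)
            black.add((origin_i + col, origin_j - row))
    return BinaryImage(black=frozenset(black), block_size=block_size)
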