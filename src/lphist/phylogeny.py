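"""UPGMA tree construction, Newick I/O, and Robinson-Foulds distance.

UPGMA (unweighted pair group method with arithmetic mean) repeatedly
merges the closest pair of clusters; the merged node sits at height d/2
and the distance from a merged cluster to any other is the size-weighted
arithmetic mean of its parts' distances.  The result is a rooted
ultrametric tree: all root-to-leaf path lengths are equal.  Ties in the
closest pair are broken by the lexicographically smallest pair of cluster
labels (a cluster is labelled by its smallest leaf name) so the output is
deterministic and independent of input order.

The Robinson-Foulds distance is the size of the symmetric difference of
the two trees' non-trivial bipartition sets, treating both trees as
unrooted (identical-but-missing splits are counted once per tree, so two
fully resolved trees on n leaves have RF at most 2(n-3)).  Branch lengths
are ignored; multifurcating trees are accepted and contribute only the
bipartitions they actually resolve.
"""

from __future__ import annotations

import io

import numpy as np
from skbio import TreeNode

from lphist.distances import DistanceMatrix


def upgma(matrix: DistanceMatrix) -> TreeNode:
    """Build a rooted ultrametric tree by average-linkage clustering."""
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("distance matrix contains non-finite entries")
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    clusters: dict[int, dict] = {
        k: {
            "node": TreeNode(name=matrix.labels[k]),
            "height": 0.0,
            "size": 1,
            "label": matrix.labels[k],
        }
        for k in range(n)
    }
    dist: dict[tuple[int, int], float] = {
        (a, b): float(matrix.values[a, b])
        for a in range(n)
        for b in range(a + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        # closest pair; ties broken by smallest (label, label) pair
        best_key = min(
            dist,
            key=lambda k: (
                dist[k],
                tuple(sorted((clusters[k[0]]["label"], clusters[k[1]]["label"]))),
            ),
        )
        a, b = best_key
        d = dist[best_key]
        height = d / 2.0
        ca, cb = clusters.pop(a), clusters.pop(b)
        ca["node"].length = height - ca["height"]
        cb["node"].length = height - cb["height"]
        merged = {
            "node": TreeNode(children=[ca["node"], cb["node"]]),
            "height": height,
            "size": ca["size"] + cb["size"],
            "label": min(ca["label"], cb["label"]),
        }
        new_dist = {}
        for k in clusters:
            da = dist[(min(a, k), max(a, k))]
            db = dist[(min(b, k), max(b, k))]
            new_dist[k] = (ca["size"] * da + cb["size"] * db) / merged["size"]
        dist = {
            key: v for key, v in dist.items() if a not in key and b not in key
        }
        for k, v in new_dist.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        clusters[next_id] = merged
        next_id += 1
    root = next(iter(clusters.values()))["node"]
    root.length = None
    return root


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree to a single-line Newick string."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(newick: str | io.TextIOBase) -> TreeNode:
    """Parse a Newick string (or open handle) into a tree.

    Leaf labels must be unique; malformed input raises ``ValueError`` with
    the parser's position information.
    """
    handle = io.StringIO(newick) if isinstance(newick, str) else newick
    try:
        tree = TreeNode.read(handle, format="newick")
    except Exception as exc:  # skbio raises its own parse error hierarchy
        raise ValueError(f"malformed Newick: {exc}") from exc
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return tree


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (implicitly unrooted) tree.

    Each split is represented by the side not containing a fixed reference
    leaf, which deduplicates the two root edges of a rooted binary tree.
    """
    leaves = frozenset(tip.name for tip in tree.tips())
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(tip.name for tip in node.tips())
        side = clade if ref not in clade else leaves - clade
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric-difference Robinson-Foulds distance between two trees."""
    leaves1 = {tip.name for tip in t1.tips()}
    leaves2 = {tip.name for tip in t2.tips()}
    if leaves1 != leaves2:
        raise ValueError(
            "leaf sets differ: "
            f"only in first = {sorted(leaves1 - leaves2)}, "
            f"only in second = {sorted(leaves2 - leaves1)}"
        )
    b1, b2 = _bipartitions(t1), _bipartitions(t2)
    return len(b1 ^ b2)
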