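"""Octree spatial index for fixed-radius neighbor queries.

The density clustering stage issues one fixed-radius query per point; on a raw
scan that is far too slow with an all-pairs scan.  The octree recursively
subdivides the cloud's bounding cube until leaves are no wider than
``leaf_size`` (or hold at most a handful of points) and prunes whole subtrees
whose cube lies outside the query sphere.  Queries return exactly the ids of
points within Euclidean distance ``radius`` of the center — verified against a
brute-force scan in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["OctreeIndex"]

_MAX_LEAF_POINTS = 16


class _Node:
    __slots__ = ("center", "half", "ids", "children")

    def __init__(self, center: np.ndarray, half: float) -> None:
        self.center = center
        self.half = half
        self.ids: np.ndarray | None = None  # set on leaves
        self.children: list["_Node"] | None = None


class OctreeIndex:
    """Octree over a fixed set of 3D points.

    Parameters
    ----------
    points
        ``(n, 3)`` coordinates to index.
    leaf_size
        Target edge length of leaf cubes, in meters.  Smaller leaves prune
        more aggressively per query but deepen the tree.
    """

    def __init__(self, points: np.ndarray, leaf_size: float = 0.26) -> None:
        if leaf_size <= 0:
            raise ValueError("leaf_size must be > 0")
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        self.points = pts
        self.leaf_size = leaf_size
        if len(pts) == 0:
            self._root = None
            return
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        center = (lo + hi) / 2.0
        half = float(max((hi - lo).max() / 2.0, leaf_size / 2.0)) * (1 + 1e-12)
        self._root = _Node(center, half)
        self._build(self._root, np.arange(len(pts)))

    def _build(self, node: _Node, ids: np.ndarray) -> None:
        if len(ids) <= _MAX_LEAF_POINTS or node.half * 2.0 <= self.leaf_size:
            node.ids = ids
            return
        node.children = []
        pts = self.points[ids]
        octant = (
            (pts[:, 0] > node.center[0]).astype(int)
            | ((pts[:, 1] > node.center[1]).astype(int) << 1)
            | ((pts[:, 2] > node.center[2]).astype(int) << 2)
        )
        qh = node.half / 2.0
        for o in range(8):
            sub = ids[octant == o]
            if len(sub) == 0:
                continue
            offset = np.array([(o & 1), (o >> 1) & 1, (o >> 2) & 1], dtype=float)
            child = _Node(node.center + (offset * 2.0 - 1.0) * qh, qh)
            self._build(child, sub)
            node.children.append(child)

    def __len__(self) -> int:
        return len(self.points)

    def radius_query(self, center: np.ndarray, radius: float) -> np.ndarray:
        """Ids of all indexed points within ``radius`` of ``center`` (sorted)."""
        if radius <= 0:
            raise ValueError("radius must be > 0")
        if self._root is None:
            return np.empty(0, dtype=int)
        c = np.asarray(center, dtype=float).reshape(3)
        out: list[np.ndarray] = []
        stack = [self._root]
        r2 = radius * radius
        while stack:
            node = stack.pop()
            # distance from query point to the node's cube
            d = np.maximum(np.abs(c - node.center) - node.half, 0.0)
            if d @ d > r2:
                continue
            # cube entirely inside the sphere: take everything below
            far = np.abs(c - node.center) + node.half
            if far @ far <= r2:
                out.append(self._collect(node))
                continue
            if node.children is not None:
                stack.extend(node.children)
            else:
                ids = node.ids
                diff = self.points[ids] - c
                out.append(ids[np.einsum("ij,ij->i", diff, diff) <= r2])
        if not out:
            return np.empty(0, dtype=int)
        return np.sort(np.concatenate(out))

    def _collect(self, node: _Node) -> np.ndarray:
        if node.ids is not None:
            return node.ids
        return np.concatenate([self._collect(ch) for ch in node.children])
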