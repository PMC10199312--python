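"""SWC I/O, the neuron tree model, branch decomposition and the two partition steps.

Coordinates are voxel-indexed (0-based, x/y/z matching image axes); physical
units (µm) enter only through ``NeuronTree.voxel_size``, so arc lengths used for
partitioning are measured in µm while geometry stays in voxel space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SwcNode",
    "NeuronTree",
    "Segment",
    "SwcParseError",
    "SwcStructureError",
    "read_swc",
    "write_swc",
    "swc_bytes",
    "decompose_branches",
    "first_partition",
    "second_partition",
    "resample_polyline",
    "polyline_arc_length",
]


class SwcParseError(ValueError):
    """Malformed SWC text (names the offending line number)."""


class SwcStructureError(ValueError):
    """Structurally invalid tree: multiple roots, dangling parents, cycles."""


@dataclass
class SwcNode:
    """One SWC record: sample id, structure type, position (voxels), radius, parent."""

    id: int
    type_code: int
    position: np.ndarray  # (3,) float, x/y/z voxel coordinates
    radius: float
    parent_id: int  # -1 for the root

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.radius < 0:
            raise ValueError(f"negative radius on node {self.id}")


class NeuronTree:
    """A rooted neuron reconstruction: SWC nodes plus the voxel size in µm.

    Invariants (checked by :meth:`validate`): unique ids, exactly one root,
    every parent id resolves, parent links are acyclic.
    """

    def __init__(
        self,
        nodes: Sequence[SwcNode],
        voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
        header: Sequence[str] = (),
    ) -> None:
        self.nodes: list[SwcNode] = list(nodes)
        self.voxel_size = np.asarray(voxel_size, dtype=float)
        self.header: list[str] = list(header)
        self._index: dict[int, SwcNode] | None = None

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> SwcNode:
        if self._index is None or len(self._index) != len(self.nodes):
            self._index = {n.id: n for n in self.nodes}
        return self._index[node_id]

    @property
    def root(self) -> SwcNode:
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SwcStructureError(f"expected exactly one root, found {len(roots)}")
        return roots[0]

    def children_map(self) -> dict[int, list[int]]:
        cm: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                cm[n.parent_id].append(n.id)
        return cm

    def tips(self) -> list[SwcNode]:
        cm = self.children_map()
        return [n for n in self.nodes if n.parent_id != -1 and not cm[n.id]]

    def bifurcations(self) -> list[SwcNode]:
        """Non-root nodes with >= 2 children (branching points)."""
        cm = self.children_map()
        return [n for n in self.nodes if n.parent_id != -1 and len(cm[n.id]) >= 2]

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes], dtype=float)

    def copy(self) -> "NeuronTree":
        return NeuronTree(
            [SwcNode(n.id, n.type_code, n.position.copy(), n.radius, n.parent_id) for n in self.nodes],
            self.voxel_size.copy(),
            list(self.header),
        )

    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise SwcStructureError("duplicate node ids")
        idset = set(ids)
        roots = 0
        for n in self.nodes:
            if n.parent_id == -1:
                roots += 1
            elif n.parent_id not in idset:
                raise SwcStructureError(f"node {n.id} has dangling parent_id {n.parent_id}")
        if roots != 1:
            raise SwcStructureError(f"expected exactly one root, found {roots}")
        # cycle check via iterative parent walk with memoization
        ok: set[int] = set()
        parent = {n.id: n.parent_id for n in self.nodes}
        for start in ids:
            seen: list[int] = []
            cur = start
            while cur != -1 and cur not in ok:
                if cur in seen:
                    raise SwcStructureError(f"cycle through node {cur}")
                seen.append(cur)
                cur = parent[cur]
            ok.update(seen)


@dataclass
class Segment:
    """An ordered polyline between two anchors — the unit of re-tracing."""

    node_positions: np.ndarray  # (n, 3) voxel coordinates
    start_anchor: np.ndarray
    end_anchor: np.ndarray
    kind: str  # "branch_piece" | "midpoint_pair"
    parent_branch_id: int
    node_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        if len(self.node_positions) < 2:
            raise ValueError("a segment needs at least 2 positions")
        gaps = np.linalg.norm(np.diff(self.node_positions, axis=0), axis=1)
        if np.any(gaps == 0):
            raise ValueError("consecutive segment positions must be distinct")
        self.start_anchor = np.asarray(self.start_anchor, dtype=float)
        self.end_anchor = np.asarray(self.end_anchor, dtype=float)


# -- I/O -------------------------------------------------------------------


def read_swc(path: str | Path, voxel_size: Sequence[float] = (1.0, 1.0, 1.0)) -> NeuronTree:
    """Parse a standard 7-column SWC file into a validated :class:`NeuronTree`.

    Comment lines (``#``) are preserved in ``tree.header`` so files round-trip.
    """
    path = Path(path)
    nodes: list[SwcNode] = []
    header: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SwcParseError(f"{path.name}:{lineno}: expected 7 fields, got {len(fields)}")
            try:
                nid = int(fields[0])
                tc = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                pid = int(fields[6])
            except ValueError as exc:
                raise SwcParseError(f"{path.name}:{lineno}: {exc}") from exc
            nodes.append(SwcNode(nid, tc, np.array([x, y, z]), r, pid))
    tree = NeuronTree(nodes, voxel_size=voxel_size, header=header)
    tree.validate()
    return tree


def swc_bytes(tree: NeuronTree) -> bytes:
    """Canonical SWC serialization (3 decimal places, topological node order)."""
    if not tree.nodes:
        raise ValueError("refusing to serialize an empty tree")
    order = _topological_order(tree)
    lines = list(tree.header)
    for n in order:
        x, y, z = n.position
        lines.append(
            f"{n.id} {n.type_code} {x:.3f} {y:.3f} {z:.3f} {n.radius:.3f} {n.parent_id}"
        )
    return ("\n".join(lines) + "\n").encode()


def write_swc(tree: NeuronTree, path: str | Path) -> None:
    """Write ``tree`` so that :func:`read_swc` reproduces ids, parents and
    positions to 3 decimals. Refuses empty trees."""
    tree.validate()
    Path(path).write_bytes(swc_bytes(tree))


def _topological_order(tree: NeuronTree) -> list[SwcNode]:
    """Nodes ordered parent-before-child (stable within the stored order)."""
    cm = tree.children_map()
    by_id = {n.id: n for n in tree.nodes}
    out: list[SwcNode] = []
    stack = [tree.root.id]
    while stack:
        nid = stack.pop()
        out.append(by_id[nid])
        stack.extend(reversed(cm[nid]))
    if len(out) != len(tree.nodes):
        raise SwcStructureError("disconnected nodes present")
    return out


# -- geometry helpers ------------------------------------------------------


def polyline_arc_length(points: np.ndarray, voxel_size: Sequence[float] = (1, 1, 1)) -> float:
    """Total arc length in µm of a polyline given in voxel coordinates."""
    pts = np.asarray(points, dtype=float) * np.asarray(voxel_size, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _cumulative_arc(points: np.ndarray, voxel_size: Sequence[float]) -> np.ndarray:
    pts = np.asarray(points, dtype=float) * np.asarray(voxel_size, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def point_at_arc(points: np.ndarray, s: float, voxel_size: Sequence[float] = (1, 1, 1)) -> np.ndarray:
    """Point at arc length ``s`` (µm) along a polyline, linearly interpolated."""
    points = np.asarray(points, dtype=float)
    cum = _cumulative_arc(points, voxel_size)
    s = float(np.clip(s, 0.0, cum[-1]))
    return np.array([np.interp(s, cum, points[:, d]) for d in range(3)])


def resample_polyline(
    points: np.ndarray, step: float, voxel_size: Sequence[float] = (1, 1, 1)
) -> np.ndarray:
    """Resample a polyline at a fixed arc-length interval (µm).

    Consecutive output points are ``step`` apart in arc length except for the
    final gap; the first and last input points are preserved exactly.
    """
    if step <= 0:
        raise ValueError("resampling step must be positive")
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    cum = _cumulative_arc(points, voxel_size)
    total = cum[-1]
    stations = np.arange(0.0, total, step)
    # guard against a terminal station coinciding with the endpoint
    if len(stations) > 1 and total - stations[-1] < 1e-9 * max(total, 1.0):
        stations = stations[:-1]
    out = np.stack([np.interp(stations, cum, points[:, d]) for d in range(3)], axis=1)
    out = np.vstack([out, points[-1]])
    out[0] = points[0]
    return out


# -- branch decomposition and partitions -----------------------------------


def decompose_branches(tree: NeuronTree) -> list[Segment]:
    """Split the tree into maximal branches between critical nodes.

    Critical nodes are the root, bifurcations (>= 2 children) and tips; every
    tree edge belongs to exactly one branch. A single-node tree yields [].
    """
    tree.validate()
    cm = tree.children_map()
    by_id = {n.id: n for n in tree.nodes}
    root = tree.root
    branches: list[Segment] = []
    # walk from each critical node downstream until the next critical node
    stack = [root.id]
    bid = 0
    while stack:
        start = stack.pop()
        for child in cm[start]:
            ids = [start, child]
            cur = child
            while len(cm[cur]) == 1:
                cur = cm[cur][0]
                ids.append(cur)
            # drop nodes that coincide with their predecessor (zero-length
            # edges, e.g. after a collapsing refinement) but keep the anchors
            kept = [ids[0]]
            for i in ids[1:]:
                if np.linalg.norm(by_id[i].position - by_id[kept[-1]].position) > 1e-12:
                    kept.append(i)
                elif i == ids[-1] and len(kept) > 1:
                    kept[-1] = i  # same position; preserve the end-anchor id
            ids = kept
            if len(ids) < 2:
                continue  # branch fully collapsed onto the start anchor
            pos = np.array([by_id[i].position for i in ids], dtype=float)
            branches.append(
                Segment(
                    node_positions=pos,
                    start_anchor=pos[0],
                    end_anchor=pos[-1],
                    kind="branch_piece",
                    parent_branch_id=bid,
                    node_ids=ids,
                )
            )
            bid += 1
            if cm[cur]:  # bifurcation: continue from it
                stack.append(cur)
    return branches


def first_partition(
    tree: NeuronTree, max_segment_len: float = 50.0
) -> list[Segment]:
    """Break every branch into pieces of arc length strictly below the cap.

    Branches are cut into the minimal number of equal-arc-length pieces with
    each cut snapped to the nearest existing reconstruction node; if snapping
    would leave a piece at or above the cap (coarse node spacing), the exact
    interpolated cut point is inserted instead.
    """
    if max_segment_len <= 0:
        raise ValueError("max_segment_len must be positive")
    pieces: list[Segment] = []
    for branch in decompose_branches(tree):
        pieces.extend(_split_branch(branch, tree.voxel_size, max_segment_len))
    return pieces


def _split_branch(branch: Segment, voxel_size: np.ndarray, max_len: float) -> list[Segment]:
    pts = branch.node_positions
    cum = _cumulative_arc(pts, voxel_size)
    total = cum[-1]
    n_pieces = int(total // max_len) + 1  # minimal n with total/n < max_len
    if n_pieces == 1:
        return [branch]
    ideal = [total * i / n_pieces for i in range(1, n_pieces)]
    # snap each ideal cut to the nearest existing node (interior only)
    cut_idx: list[int | float] = []
    for s in ideal:
        j = int(np.argmin(np.abs(cum - s)))
        j = min(max(j, 1), len(pts) - 2)
        cut_idx.append(j)
    cuts = sorted(set(int(j) for j in cut_idx))
    boundaries = [0] + cuts + [len(pts) - 1]
    # guard the strict bound: insert exact cut points where snapping failed
    pieces: list[Segment] = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if b <= a:
            continue
        sub = pts[a : b + 1]
        ids = branch.node_ids[a : b + 1] if branch.node_ids else []
        pieces.extend(
            _enforce_cap(sub, ids, branch.parent_branch_id, voxel_size, max_len)
        )
    return pieces


def _enforce_cap(
    pts: np.ndarray,
    ids: list[int],
    branch_id: int,
    voxel_size: np.ndarray,
    max_len: float,
) -> list[Segment]:
    length = polyline_arc_length(pts, voxel_size)
    if length < max_len:
        return [
            Segment(pts, pts[0], pts[-1], "branch_piece", branch_id, node_ids=list(ids))
        ]
    n = int(length // max_len) + 1
    cum = _cumulative_arc(pts, voxel_size)
    out: list[Segment] = []
    prev = pts[0]
    prev_s = 0.0
    for i in range(1, n + 1):
        s = length * i / n
        sub_mask = (cum > prev_s) & (cum < s)
        body = pts[sub_mask]
        nxt = point_at_arc(pts, s, voxel_size) if i < n else pts[-1]
        piece_pts = np.vstack([prev[None, :], body, nxt[None, :]])
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(piece_pts, axis=0), axis=1) > 1e-12]
        )
        out.append(
            Segment(piece_pts[keep], piece_pts[0], piece_pts[-1], "branch_piece", branch_id)
        )
        prev, prev_s = nxt, s
    return out


def path_midpoint(points: np.ndarray, voxel_size: Sequence[float] = (1, 1, 1)) -> np.ndarray:
    """The half-arc-length point of a polyline (interpolated)."""
    cum = _cumulative_arc(np.asarray(points, float), voxel_size)
    return point_at_arc(points, cum[-1] / 2.0, voxel_size)


def second_partition(
    traced_paths: Sequence[np.ndarray],
    adjacency: Sequence[tuple[int, int]] | None = None,
    voxel_size: Sequence[float] = (1, 1, 1),
) -> tuple[list[np.ndarray], list[tuple[int, int]]]:
    """Midpoint partition: one half-arc midpoint per first-pass path, paired
    for every pair of adjacent paths.

    ``adjacency`` lists index pairs of paths that share a first-pass anchor;
    when omitted, the paths are assumed to form a single chain in order. An
    isolated path yields a midpoint but no pair.

    Returns ``(midpoints, pairs)`` where ``pairs`` holds path-index pairs;
    the pair's endpoints are ``midpoints[i], midpoints[j]``.
    """
    mids = [path_midpoint(p, voxel_size) for p in traced_paths]
    if adjacency is None:
        adjacency = [(i, i + 1) for i in range(len(traced_paths) - 1)]
    return mids, list(adjacency)
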