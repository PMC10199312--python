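"""The four-stage refinement pipeline.

Stages: (1) first partition — branches are broken into pieces shorter than
``max_segment_len`` µm; (2) first re-tracing — each piece is re-traced by the
GD tracer between its (possibly deviated) anchors, which centers the piece
body on the signal while the anchors stay put; (3) second partition — the
half-arc midpoints of the first-pass curves become new, on-signal anchors;
(4) second re-tracing — adjacent midpoints are traced pairwise, which also
carries the path across the original anchors, including bifurcations, whose
refined position is recovered as the divergence point of the two curves
crossing the junction. The refined paths are stitched back into a valid tree
with the root and every terminal bit-identical to the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .swc_core import (
    NeuronTree,
    Segment,
    SwcNode,
    decompose_branches,
    first_partition,
    path_midpoint,
    polyline_arc_length,
    resample_polyline,
    second_partition,
)
from .gd_tracer import Curve, EnergyParams, ImageBlock, total_energy, trace

log = logging.getLogger(__name__)

__all__ = [
    "RefineConfig",
    "RefineReport",
    "SegmentRecord",
    "RefineError",
    "crop_block",
    "retrace_step1",
    "retrace_step2",
    "relocate_bifurcation",
    "stitch",
    "refine_neuron",
]


class RefineError(RuntimeError):
    """Structural failure during refinement (reports completed stages)."""

    def __init__(self, message: str, stages_completed: Sequence[str] = ()) -> None:
        super().__init__(message)
        self.stages_completed = list(stages_completed)


def _step1_defaults() -> EnergyParams:
    # image term dominates: the first pass must find the correct signal
    return EnergyParams(alpha=1.0, beta=0.2, gamma=0.2)


def _step2_defaults() -> EnergyParams:
    # endpoints are now on-signal: smoothness/length weigh as much as image
    return EnergyParams(alpha=0.5, beta=0.5, gamma=0.5)


@dataclass
class RefineConfig:
    max_segment_len: float = 50.0  # µm
    step1_params: EnergyParams = field(default_factory=_step1_defaults)
    step2_params: EnergyParams = field(default_factory=_step2_defaults)
    crop_margin: int = 16  # voxels around each segment's bounding box
    resample_step_out: float | None = None  # µm; None keeps traced spacing


@dataclass
class SegmentRecord:
    segment_id: int
    stage: str  # "step1" | "step2" | "junction"
    fallback: str | None
    pre_energy: float
    post_energy: float
    n_points_before: int
    n_points_after: int


@dataclass
class RefineReport:
    segments: list[SegmentRecord] = field(default_factory=list)
    n_segments: int = 0
    n_traces: int = 0
    n_fallbacks: int = 0
    stages_completed: list[str] = field(default_factory=list)


# -- cropping --------------------------------------------------------------


def crop_block(volume: ImageBlock | np.ndarray, points: np.ndarray | Segment, margin: int) -> ImageBlock:
    """Sub-block covering the points' bounding box dilated by ``margin``
    voxels and clipped to the volume; the origin maps local back to global."""
    if isinstance(points, Segment):
        points = points.node_positions
    vol = volume if isinstance(volume, ImageBlock) else ImageBlock(np.asarray(volume))
    pts = np.asarray(points, dtype=float)
    shape = np.array(vol.shape)
    if np.all(pts.max(axis=0) < 0) or np.all(pts.min(axis=0) >= shape):
        raise ValueError("segment lies fully outside the volume")
    lo = np.maximum(np.floor(pts.min(axis=0)).astype(int) - margin, 0)
    hi = np.minimum(np.ceil(pts.max(axis=0)).astype(int) + margin, shape - 1)
    data = vol.data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    return ImageBlock(data, origin=vol.origin + lo, voxel_size=vol.voxel_size)


def _trace_global(volume: ImageBlock, span: np.ndarray, p0, p1, params, margin):
    """Trace p0→p1 inside a crop around ``span``; returns (curve pts global,
    pre/post energies). Raises on degenerate (dark) blocks."""
    block = crop_block(volume, span, margin)
    if block.imax <= 0:
        raise ValueError("all-zero image block")
    off = block.origin - volume.origin
    init = Curve(np.vstack([np.asarray(p0) - off, np.asarray(p1) - off]))
    pre = total_energy(Curve(np.asarray(span) - off), block, params)
    curve = trace(block, init.control_points[0], init.control_points[1], params)
    post = total_energy(curve, block, params)
    return curve.control_points + off, pre, post


# -- arc helpers -----------------------------------------------------------


def _split_at_half(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a polyline at its half-arc midpoint (midpoint in both halves)."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    half = cum[-1] / 2.0
    mid = path_midpoint(pts)
    i = int(np.searchsorted(cum, half))
    first = np.vstack([pts[:i], mid])
    second = np.vstack([mid, pts[i:]])
    return _dedupe(first), _dedupe(second)


def _dedupe(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, float)
    if len(pts) < 2:
        return pts
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
    out = pts[keep]
    if len(out) < 2:  # all points coincided; keep endpoints
        out = pts[[0, -1]]
    return out


def _resample_half_voxel(points: np.ndarray) -> np.ndarray:
    pts = _dedupe(points)
    length = polyline_arc_length(pts)
    if length <= 0.5 or len(pts) < 2:
        return pts
    return resample_polyline(pts, 0.5)


# -- re-tracing steps ------------------------------------------------------


def retrace_step1(
    segments: Sequence[Segment],
    volume: ImageBlock,
    config: RefineConfig,
    report: RefineReport | None = None,
) -> list[np.ndarray]:
    """First re-tracing: one GD trace per partitioned piece, anchored at the
    piece's original endpoints. A failing trace falls back to the original
    polyline and is flagged in the report."""
    report = report if report is not None else RefineReport()
    curves: list[np.ndarray] = []
    for i, seg in enumerate(segments):
        pts = seg.node_positions
        try:
            curve, pre, post = _trace_global(
                volume, pts, pts[0], pts[-1], config.step1_params, config.crop_margin
            )
            rec = SegmentRecord(i, "step1", None, pre, post, len(pts), len(curve))
        except Exception as exc:  # degenerate block or tracer failure
            log.warning("step1 trace %d fell back to input polyline: %s", i, exc)
            curve = pts.copy()
            rec = SegmentRecord(i, "step1", str(exc), float("nan"), float("nan"), len(pts), len(pts))
            report.n_fallbacks += 1
        report.segments.append(rec)
        report.n_traces += 1
        curves.append(curve)
    return curves


def retrace_step2(
    midpoint_pairs: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    volume: ImageBlock,
    config: RefineConfig,
    report: RefineReport | None = None,
) -> list[np.ndarray]:
    """Second re-tracing between adjacent midpoints.

    Each entry is ``(p0, p1, span)`` where ``span`` is the first-pass
    geometry covering the pair (used for cropping and as the fallback path).
    """
    report = report if report is not None else RefineReport()
    curves: list[np.ndarray] = []
    for i, (p0, p1, span) in enumerate(midpoint_pairs):
        try:
            curve, pre, post = _trace_global(
                volume, span, p0, p1, config.step2_params, config.crop_margin
            )
            rec = SegmentRecord(i, "step2", None, pre, post, len(span), len(curve))
        except Exception as exc:
            log.warning("step2 trace %d fell back to step-1 span: %s", i, exc)
            curve = _dedupe(np.asarray(span, float))
            rec = SegmentRecord(i, "step2", str(exc), float("nan"), float("nan"), len(span), len(span))
            report.n_fallbacks += 1
        report.segments.append(rec)
        report.n_traces += 1
        curves.append(curve)
    return curves


# -- bifurcation relocation ------------------------------------------------


def relocate_bifurcation(
    curves: Sequence[np.ndarray],
    original_position: np.ndarray,
    tolerance: float = 1.0,
):
    """Recover a junction from the >= 2 step-2 curves that cross it.

    All curves start at the same parent-branch midpoint and end at the
    midpoint of a different child branch. After arc-length alignment (0.5
    voxel sampling) the junction is the last point of their maximal common
    prefix (pointwise spread <= ``tolerance``); the prefix average becomes
    the refined parent-side polyline, the remainders the child-side ones.

    Returns ``(junction, parent_poly, child_polys, fallback)``; when the
    curves share no prefix the original bifurcation is snapped to the nearest
    point on either curve instead and ``fallback`` is True.
    """
    if len(curves) < 2:
        raise ValueError("need at least two curves crossing the junction")
    rs = [_resample_half_voxel(c) for c in curves]
    n = min(len(r) for r in rs)
    stack = np.stack([r[:n] for r in rs])  # (ncurves, n, 3)
    spread = stack.max(axis=0) - stack.min(axis=0)
    ok = np.linalg.norm(spread, axis=1) <= tolerance
    k = 0
    while k + 1 < n and ok[k + 1]:
        k += 1
    if k == 0:
        # no common prefix: snap the original bifurcation onto the curves
        best = None
        for ci, r in enumerate(rs):
            d = np.linalg.norm(r - original_position, axis=1)
            j = int(np.argmin(d))
            if best is None or d[j] < best[0]:
                best = (d[j], ci, j)
        _, ci, j = best
        junction = rs[ci][j].copy()
        parent_poly = np.vstack([rs[ci][: j + 1], junction[None]]) if j > 0 else np.vstack(
            [rs[ci][0][None], junction[None]]
        )
        child_polys = []
        for r in rs:
            jj = int(np.argmin(np.linalg.norm(r - junction, axis=1)))
            child_polys.append(_dedupe(np.vstack([junction[None], r[jj:]])))
        return junction, _dedupe(parent_poly), child_polys, True
    junction = stack[:, k].mean(axis=0)
    parent_poly = np.vstack([stack[:, : k + 1].mean(axis=0), junction[None]])
    child_polys = [_dedupe(np.vstack([junction[None], r[k:]])) for r in rs]
    return junction, _dedupe(parent_poly), child_polys, False


# -- stitching -------------------------------------------------------------


def _arc_fractions(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum / cum[-1] if cum[-1] > 0 else np.linspace(0, 1, len(points))


def stitch(
    refined_branches: dict[int, np.ndarray],
    tree: NeuronTree,
    junction_positions: dict[int, np.ndarray],
    resample_step_out: float | None = None,
) -> NeuronTree:
    """Assemble refined branch polylines back into a valid NeuronTree.

    ``refined_branches`` maps branch index (decompose order) to its refined
    polyline running start→end; ``junction_positions`` maps original
    bifurcation node ids to their relocated positions. Root/tip positions and
    the branching topology are preserved; node ids are renumbered
    consecutively; radii are carried over by relative arc length.
    """
    branches = decompose_branches(tree)
    root = tree.root
    nodes: list[SwcNode] = [SwcNode(1, root.type_code, root.position.copy(), root.radius, -1)]
    new_id_of: dict[int, int] = {root.id: 1}
    next_id = 2
    for bi, b in enumerate(branches):
        poly = _dedupe(np.asarray(refined_branches[bi], float))
        if resample_step_out is not None and polyline_arc_length(poly, tree.voxel_size) > resample_step_out:
            poly = resample_polyline(poly, resample_step_out, tree.voxel_size)
        orig = b.node_positions
        orig_r = np.array([tree.node(i).radius for i in b.node_ids])
        fr_new = _arc_fractions(poly)
        fr_old = _arc_fractions(orig)
        radii = np.interp(fr_new, fr_old, orig_r)
        end_tc = tree.node(b.node_ids[-1]).type_code
        start_new = new_id_of[b.node_ids[0]]
        prev = start_new
        for j in range(1, len(poly)):
            nodes.append(SwcNode(next_id, end_tc, poly[j].copy(), float(radii[j]), prev))
            prev = next_id
            next_id += 1
        end_node = nodes[-1]
        end_node.radius = float(orig_r[-1])
        new_id_of[b.node_ids[-1]] = prev
    out = NeuronTree(nodes, tree.voxel_size.copy(), list(tree.header))
    out.validate()
    _check_topology(tree, out)
    return out


def _check_topology(before: NeuronTree, after: NeuronTree) -> None:
    nb, na = len(before.bifurcations()), len(after.bifurcations())
    tb, ta = len(before.tips()), len(after.tips())
    problems = []
    if nb != na:
        problems.append(f"bifurcations {nb} -> {na}")
    if tb != ta:
        problems.append(f"tips {tb} -> {ta}")
    if not np.allclose(before.root.position, after.root.position):
        problems.append("root moved")
    if problems:
        raise RefineError("topology changed during stitch: " + "; ".join(problems))


# -- top-level pipeline ----------------------------------------------------


def refine_neuron(
    tree: NeuronTree,
    volume: ImageBlock | np.ndarray,
    config: RefineConfig | None = None,
) -> tuple[NeuronTree, RefineReport]:
    """Run the full refinement on one reconstruction.

    Only internal nodes move: the soma (root) and every terminal are assumed
    correct and are preserved bit-identically, as is the branching topology.
    """
    config = config or RefineConfig()
    vol = volume if isinstance(volume, ImageBlock) else ImageBlock(np.asarray(volume))
    tree.validate()
    report = RefineReport()
    branches = decompose_branches(tree)
    if not branches:
        report.stages_completed.append("noop")
        return tree.copy(), report
    if len(branches) == 1 and len(branches[0].node_positions) == 2:
        # a single edge between two fixed endpoints: nothing refinable
        report.stages_completed.append("noop")
        return tree.copy(), report

    # stage 1: partition
    pieces = first_partition(tree, config.max_segment_len)
    by_branch: dict[int, list[Segment]] = {}
    for p in pieces:
        by_branch.setdefault(p.parent_branch_id, []).append(p)
    report.n_segments = len(pieces)
    report.stages_completed.append("first_partition")

    # stage 2: first re-tracing (per piece, branch order from the root)
    flat: list[Segment] = [p for bi in range(len(branches)) for p in by_branch[bi]]
    flat_curves = retrace_step1(flat, vol, config, report)
    curves_by_branch: dict[int, list[np.ndarray]] = {}
    k = 0
    for bi in range(len(branches)):
        m = len(by_branch[bi])
        curves_by_branch[bi] = flat_curves[k : k + m]
        k += m
    report.stages_completed.append("retrace_step1")

    # stage 3: midpoint partition
    mids: dict[int, list[np.ndarray]] = {
        bi: [path_midpoint(c) for c in cs] for bi, cs in curves_by_branch.items()
    }
    report.stages_completed.append("second_partition")

    # stage 4: second re-tracing — within-branch pairs ...
    within_pairs = []
    within_index: dict[tuple[int, int], int] = {}
    for bi, cs in curves_by_branch.items():
        for pi in range(len(cs) - 1):
            span = _dedupe(
                np.vstack([_split_at_half(cs[pi])[1], _split_at_half(cs[pi + 1])[0]])
            )
            within_index[(bi, pi)] = len(within_pairs)
            within_pairs.append((mids[bi][pi], mids[bi][pi + 1], span))
    # ... and cross-junction pairs (one per child of each bifurcation)
    child_branches: dict[int, list[int]] = {}
    branch_by_end: dict[int, int] = {}
    for bi, b in enumerate(branches):
        child_branches.setdefault(b.node_ids[0], []).append(bi)
        branch_by_end[b.node_ids[-1]] = bi
    junction_pairs = []
    junction_index: dict[tuple[int, int], int] = {}  # (junction node id, child bi)
    for bif in tree.bifurcations():
        jid = bif.id
        if jid not in branch_by_end:
            continue
        pbi = branch_by_end[jid]
        p_last = curves_by_branch[pbi][-1]
        for cbi in child_branches.get(jid, []):
            c_first = curves_by_branch[cbi][0]
            span = _dedupe(np.vstack([_split_at_half(p_last)[1], _split_at_half(c_first)[0]]))
            junction_index[(jid, cbi)] = len(junction_pairs)
            junction_pairs.append((mids[pbi][-1], mids[cbi][0], span))
    all_pairs = within_pairs + junction_pairs
    all_curves = retrace_step2(all_pairs, vol, config, report)
    within_curves = all_curves[: len(within_pairs)]
    junction_curves = all_curves[len(within_pairs) :]
    report.stages_completed.append("retrace_step2")

    # bifurcation relocation
    junction_positions: dict[int, np.ndarray] = {}
    parent_polys: dict[int, np.ndarray] = {}  # by parent branch index
    child_polys: dict[tuple[int, int], np.ndarray] = {}  # (junction id, child bi)
    for bif in tree.bifurcations():
        jid = bif.id
        if jid not in branch_by_end:
            continue
        cbis = child_branches.get(jid, [])
        curves = [junction_curves[junction_index[(jid, cbi)]] for cbi in cbis]
        junction, ppoly, cpolys, fb = relocate_bifurcation(curves, bif.position)
        if fb:
            report.n_fallbacks += 1
            report.segments.append(
                SegmentRecord(jid, "junction", "no common prefix", float("nan"), float("nan"), 0, 0)
            )
        junction_positions[jid] = junction
        parent_polys[branch_by_end[jid]] = ppoly
        for cbi, cp in zip(cbis, cpolys):
            child_polys[(jid, cbi)] = cp
    report.stages_completed.append("relocate_bifurcation")

    # assemble refined branch polylines
    refined: dict[int, np.ndarray] = {}
    cm = tree.children_map()
    tip_ids = {t.id for t in tree.tips()}
    for bi, b in enumerate(branches):
        cs = curves_by_branch[bi]
        j0, j1 = b.node_ids[0], b.node_ids[-1]
        parts: list[np.ndarray] = []
        if (j0, bi) in child_polys:
            parts.append(child_polys[(j0, bi)])
        else:  # root-anchored: splice the first-pass outer half
            parts.append(_split_at_half(cs[0])[0])
        for pi in range(len(cs) - 1):
            parts.append(within_curves[within_index[(bi, pi)]])
        if j1 in tip_ids:
            parts.append(_split_at_half(cs[-1])[1])
        elif bi in parent_polys:
            parts.append(parent_polys[bi])
        else:  # bifurcation end without relocation info (should not happen)
            parts.append(_split_at_half(cs[-1])[1])
        refined[bi] = _dedupe(np.vstack(parts))

    out = stitch(refined, tree, junction_positions, config.resample_step_out)
    report.stages_completed.append("stitch")
    return out, report
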