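"""Metric suite and baselines for reconstruction refinement.

Metrics compare a test reconstruction against ground truth after resampling
both to a common arc-length interval (2 µm by default): mean nearest-point
skeleton deviation, bifurcation deviation between topologically corresponding
junctions, radius / intensity extraction, the volume-overlap information
extraction rate, and storage size. The module also provides the Mean-Shift
(MS) baseline, a simplified auto-parameter Mean-Shift (AMS) variant, MIP
export and a benchmark driver.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .swc_core import (
    NeuronTree,
    SwcNode,
    decompose_branches,
    polyline_arc_length,
    resample_polyline,
    swc_bytes,
)
from .gd_tracer import ImageBlock, trilinear

log = logging.getLogger(__name__)

__all__ = [
    "MetricsRecord",
    "skeleton_deviation",
    "bifurcation_deviation",
    "radius_estimate",
    "intensity_extraction",
    "information_extraction_rate",
    "storage_size",
    "mean_shift_refine",
    "auto_mean_shift_refine",
    "make_mip",
    "run_benchmark",
    "resample_tree",
]


@dataclass
class MetricsRecord:
    sample_id: int
    method: str
    case_label: str
    skeleton_deviation: float
    bifurcation_deviation: float
    radius_mae: float
    intensity_mean: float
    info_extraction_rate: float
    node_count: int
    file_bytes: int
    failed: bool = False


# -- resampling helpers ----------------------------------------------------


def _branch_radii(tree: NeuronTree, branch) -> np.ndarray:
    if branch.node_ids:
        return np.array([tree.node(i).radius for i in branch.node_ids])
    return np.full(len(branch.node_positions), 1.0)


def resampled_points(
    tree: NeuronTree, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """All branch polylines resampled at ``step`` µm; returns (points, radii)."""
    pts_all, rad_all = [], []
    branches = decompose_branches(tree)
    if not branches:
        p = tree.positions()
        r = np.array([n.radius for n in tree.nodes])
        return p, r
    for b in branches:
        pts = b.node_positions
        length = polyline_arc_length(pts, tree.voxel_size)
        rs = _branch_radii(tree, b)
        if length <= step:
            new = np.vstack([pts[0], pts[-1]])
            new_r = np.array([rs[0], rs[-1]])
        else:
            new = resample_polyline(pts, step, tree.voxel_size)
            cum = np.concatenate(
                [[0], np.cumsum(np.linalg.norm(np.diff(pts * tree.voxel_size, axis=0), axis=1))]
            )
            new_cum = np.concatenate(
                [[0], np.cumsum(np.linalg.norm(np.diff(new * tree.voxel_size, axis=0), axis=1))]
            )
            new_r = np.interp(new_cum, cum, rs)
        pts_all.append(new)
        rad_all.append(new_r)
    return np.vstack(pts_all), np.concatenate(rad_all)


def resample_tree(tree: NeuronTree, step: float) -> NeuronTree:
    """Rebuild the tree with every branch resampled at ``step`` µm while
    preserving topology (junction nodes shared, radii interpolated)."""
    branches = decompose_branches(tree)
    if not branches:
        return tree.copy()
    root = tree.root
    nodes: list[SwcNode] = [SwcNode(1, root.type_code, root.position.copy(), root.radius, -1)]
    anchor_new_id = {root.id: 1}
    next_id = 2
    for b in branches:
        pts = b.node_positions
        rs = _branch_radii(tree, b)
        length = polyline_arc_length(pts, tree.voxel_size)
        if length <= step:
            new, new_r = np.vstack([pts[0], pts[-1]]), np.array([rs[0], rs[-1]])
        else:
            new = resample_polyline(pts, step, tree.voxel_size)
            cum = np.concatenate(
                [[0], np.cumsum(np.linalg.norm(np.diff(pts * tree.voxel_size, axis=0), axis=1))]
            )
            ncum = np.concatenate(
                [[0], np.cumsum(np.linalg.norm(np.diff(new * tree.voxel_size, axis=0), axis=1))]
            )
            new_r = np.interp(ncum, cum, rs)
        start_id = anchor_new_id[b.node_ids[0]]
        prev = start_id
        end_tc = tree.node(b.node_ids[-1]).type_code
        for j in range(1, len(new)):
            nodes.append(SwcNode(next_id, end_tc, new[j].copy(), float(new_r[j]), prev))
            prev = next_id
            next_id += 1
        anchor_new_id[b.node_ids[-1]] = prev
    out = NeuronTree(nodes, tree.voxel_size.copy(), list(tree.header))
    out.validate()
    return out


def _polyline_segments(tree: NeuronTree, step: float | None):
    """Segment endpoint arrays (A, B) of all (optionally resampled) branches."""
    a_list, b_list = [], []
    branches = decompose_branches(tree)
    if not branches:
        p = tree.positions()
        return p, p
    for b in branches:
        pts = b.node_positions
        if step is not None and polyline_arc_length(pts, tree.voxel_size) > step:
            pts = resample_polyline(pts, step, tree.voxel_size)
        a_list.append(pts[:-1])
        b_list.append(pts[1:])
    return np.vstack(a_list), np.vstack(b_list)


def points_to_polyline_distance(points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest polyline segment (vectorized)."""
    p = points[:, None, :]  # (n,1,3)
    a = seg_a[None, :, :]
    ab = (seg_b - seg_a)[None, :, :]
    denom = np.maximum(np.sum(ab * ab, axis=2), 1e-24)
    t = np.clip(np.sum((p - a) * ab, axis=2) / denom, 0.0, 1.0)
    proj = a + t[:, :, None] * ab
    d = np.linalg.norm(p - proj, axis=2)
    return d.min(axis=1)


# -- deviation metrics -----------------------------------------------------


def skeleton_deviation(test: NeuronTree, gt: NeuronTree, resample_step: float = 2.0) -> float:
    """Mean distance (voxels) from the resampled test skeleton to the nearest
    point on the ground-truth polyline (point-to-segment)."""
    if not test.nodes or not gt.nodes:
        raise ValueError("skeleton_deviation needs non-empty trees")
    pts, _ = resampled_points(test, resample_step)
    a, b = _polyline_segments(gt, None)
    if len(a) == 0 or np.array_equal(a, b):
        # degenerate single-point ground truth
        return float(np.mean(np.linalg.norm(pts - a[0], axis=1)))
    return float(points_to_polyline_distance(pts, a, b).mean())


def _ordered_bifurcations(tree: NeuronTree) -> list[np.ndarray]:
    """Bifurcation positions in deterministic pre-order (children in stored
    order) — the topological correspondence used for matching."""
    cm = tree.children_map()
    out = []
    stack = [tree.root.id]
    while stack:
        nid = stack.pop()
        kids = cm[nid]
        if len(kids) >= 2 and tree.node(nid).parent_id != -1:
            out.append(tree.node(nid).position)
        stack.extend(reversed(kids))
    return out


def bifurcation_deviation(test: NeuronTree, gt: NeuronTree) -> float:
    """Mean distance between topologically corresponding bifurcation points.

    Returns NaN when neither tree has a bifurcation; raises on a topology
    mismatch (refinement preserves topology, so counts must agree).
    """
    bt = _ordered_bifurcations(test)
    bg = _ordered_bifurcations(gt)
    if len(bt) != len(bg):
        raise ValueError(
            f"topology mismatch: {len(bt)} vs {len(bg)} bifurcation points"
        )
    if not bt:
        return float("nan")
    return float(np.mean([np.linalg.norm(a - b) for a, b in zip(bt, bg)]))


# -- intensity-based metrics ----------------------------------------------

_SPHERE_OFFSETS: dict[float, np.ndarray] = {}


def _sphere_offsets(r: float) -> np.ndarray:
    key = round(r, 3)
    if key not in _SPHERE_OFFSETS:
        n = int(np.floor(r))
        ax = np.arange(-n, n + 1)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        q = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        _SPHERE_OFFSETS[key] = q[np.sum(q * q, axis=1) <= r * r]
    return _SPHERE_OFFSETS[key]


def radius_estimate(
    tree: NeuronTree,
    image: ImageBlock,
    bg_threshold: float,
    r_max: float = 5.0,
) -> NeuronTree:
    """Per-node radius: the largest r (0.5-voxel grid) whose ball around the
    node is at least 95% above ``bg_threshold``; 0 in fully dark regions."""
    out = tree.copy()
    shape = np.array(image.shape)
    dark = 0
    for n in out.nodes:
        est = 0.0
        for r in np.arange(0.5, r_max + 1e-9, 0.5):
            q = np.round(n.position).astype(int) + _sphere_offsets(r)
            q = q[np.all((q >= 0) & (q < shape), axis=1)]
            if len(q) == 0:
                break
            frac = np.mean(image.data[q[:, 0], q[:, 1], q[:, 2]] > bg_threshold)
            if frac >= 0.95:
                est = float(r)
            else:
                break
        if est == 0.0:
            dark += 1
        n.radius = est
    if dark:
        log.debug("radius_estimate: %d node(s) in dark regions got radius 0", dark)
    return out


def intensity_extraction(tree: NeuronTree, image: ImageBlock) -> float:
    """Mean trilinearly interpolated image intensity at the node positions."""
    return float(np.mean(trilinear(image.data, tree.positions())))


def information_extraction_rate(
    test: NeuronTree, gt: NeuronTree, resample_step: float = 2.0
) -> float:
    """Fraction of the ground-truth tube volume covered by the test tube.

    Both skeletons are resampled at ``resample_step`` µm and voxelized as
    unions of spheres carrying their local radii; the rate is
    ``|S_test ∩ S_gt| / |S_gt|``.
    """
    gpts, grad = resampled_points(gt, resample_step)
    tpts, trad = resampled_points(test, resample_step)
    if np.all(grad <= 0):
        raise ValueError("ground-truth radii must be positive for the volume overlap")
    rmax = float(max(grad.max(), trad.max() if len(trad) else 0.0))
    lo = np.floor(np.minimum(gpts.min(0), tpts.min(0)) - rmax).astype(int)
    hi = np.ceil(np.maximum(gpts.max(0), tpts.max(0)) + rmax).astype(int)
    ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    vox = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1).astype(float)

    def covered(centers, radii):
        d, i = cKDTree(centers).query(vox)
        return d <= radii[i]

    s_gt = covered(gpts, grad)
    if not s_gt.any():
        raise ValueError("empty ground-truth volume")
    s_test = covered(tpts, trad)
    return float(np.sum(s_test & s_gt) / np.sum(s_gt))


def storage_size(tree: NeuronTree) -> tuple[int, int]:
    """(node count, byte size of the canonical SWC serialization)."""
    return len(tree.nodes), len(swc_bytes(tree))


# -- baselines -------------------------------------------------------------


def _window_centroid(image: ImageBlock, c: np.ndarray, r: float):
    shape = np.array(image.shape)
    lo = np.maximum(np.ceil(c - r).astype(int), 0)
    hi = np.minimum(np.floor(c + r).astype(int), shape - 1)
    if np.any(lo > hi):
        return None
    ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    q = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d2 = np.sum((q - c) ** 2, axis=1)
    q = q[d2 <= r * r]
    if len(q) == 0:
        return None
    w = image.data[q[:, 0], q[:, 1], q[:, 2]].astype(float)
    tot = w.sum()
    if tot <= 0:
        return None
    return (q * w[:, None]).sum(axis=0) / tot


def _mean_shift_node(image: ImageBlock, start: np.ndarray, radius: float, max_iters: int) -> np.ndarray:
    """Iterate c <- centroid of the radius-ball around c. The searching
    distance also constrains the solution space: the node never ends farther
    than ``radius`` from where it started."""
    c = start.copy()
    for _ in range(max_iters):
        cen = _window_centroid(image, c, radius)
        if cen is None:
            break
        step = cen - start
        dist = np.linalg.norm(step)
        if dist > radius:  # clamp to the allowed solution ball
            cen = start + step * (radius / dist)
        if np.linalg.norm(cen - c) < 0.1:
            c = cen
            break
        c = cen
    return c


def mean_shift_refine(
    tree: NeuronTree,
    image: ImageBlock,
    search_radius: float = 5.0,
    max_iters: int = 30,
) -> NeuronTree:
    """Classic Mean-Shift baseline: every interior node is moved iteratively
    to the intensity-weighted centroid of its ``search_radius`` ball until it
    shifts less than 0.1 voxel, within a solution ball of ``search_radius``
    around its start. Root and tips stay fixed; topology unchanged."""
    if search_radius <= 0:
        raise ValueError("search_radius must be positive")
    out = tree.copy()
    cm = out.children_map()
    root_id = out.root.id
    for n in out.nodes:
        if n.id == root_id or not cm[n.id]:
            continue
        n.position = _mean_shift_node(image, n.position.astype(float), search_radius, max_iters)
    return out


def auto_mean_shift_refine(
    tree: NeuronTree, image: ImageBlock, max_iters: int = 30, bg_threshold: float | None = None
) -> NeuronTree:
    """Simplified auto-parameter Mean-Shift: branches are first resampled at
    1-voxel steps (adding nodes), then each node mean-shifts with a window of
    twice its locally estimated radius (minimum 2 voxels)."""
    if bg_threshold is None:
        data = image.data
        bg_threshold = float(data.min()) + 0.5 * (float(data.max()) - float(data.min()))
    dense = resample_tree(tree, 1.0)
    with_r = radius_estimate(dense, image, bg_threshold)
    out = dense.copy()
    cm = out.children_map()
    root_id = out.root.id
    for n, nr in zip(out.nodes, with_r.nodes):
        if n.id == root_id or not cm[n.id]:
            continue
        win = max(2.0, 2.0 * nr.radius)
        n.position = _mean_shift_node(image, n.position.astype(float), win, max_iters)
    return out


# -- MIP -------------------------------------------------------------------

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def make_mip(volume, axis: str = "z") -> np.ndarray:
    """Maximum intensity projection of a volume (``ImageBlock`` or array
    indexed [x,y,z]) along one axis; returned as a 2D array."""
    data = volume.data if isinstance(volume, ImageBlock) else np.asarray(volume)
    return np.max(data, axis=_AXIS_INDEX[axis])


# -- benchmark driver ------------------------------------------------------


def _method_registry() -> dict[str, Callable]:
    from .pipeline import RefineConfig, refine_neuron

    def run_nrrs(sample):
        refined, _ = refine_neuron(sample.perturbed, sample.image, RefineConfig())
        return refined

    return {
        "identity": lambda s: s.perturbed.copy(),
        "nrrs": run_nrrs,
        "ms": lambda s: mean_shift_refine(s.perturbed, s.image, search_radius=5.0),
        "ams": lambda s: auto_mean_shift_refine(
            s.perturbed, s.image, bg_threshold=_sample_threshold(s)
        ),
    }


def _sample_threshold(sample) -> float:
    tube = sample.gen_params.get("tube") if sample.gen_params else None
    if tube:
        return tube["background_level"] + 0.5 * (
            tube["peak_intensity"] - tube["background_level"]
        )
    data = sample.image.data
    return float(data.min()) + 0.5 * (float(data.max()) - float(data.min()))


def evaluate_tree(
    sample, tree: NeuronTree, method: str, sample_id: int, resample_step: float = 2.0
) -> MetricsRecord:
    """All metrics of one refined tree against the sample's ground truth."""
    thr = _sample_threshold(sample)
    est = radius_estimate(tree, sample.image, thr)
    gt_r = np.array([n.radius for n in sample.ground_truth.nodes])
    # compare estimated radii at test nodes with the local ground-truth radius
    gpts = sample.ground_truth.positions()
    kd = cKDTree(gpts)
    _, idx = kd.query(est.positions())
    radius_mae = float(np.mean(np.abs(np.array([n.radius for n in est.nodes]) - gt_r[idx])))
    nc, fb = storage_size(tree)
    return MetricsRecord(
        sample_id=sample_id,
        method=method,
        case_label=sample.case_label,
        skeleton_deviation=skeleton_deviation(tree, sample.ground_truth, resample_step),
        bifurcation_deviation=bifurcation_deviation(tree, sample.ground_truth),
        radius_mae=radius_mae,
        intensity_mean=intensity_extraction(tree, sample.image),
        info_extraction_rate=information_extraction_rate(
            tree, sample.ground_truth, resample_step
        ),
        node_count=nc,
        file_bytes=fb,
    )


def run_benchmark(
    dataset: Sequence,
    methods: Sequence[str] = ("identity", "nrrs", "ms", "ams"),
    out_path: str | Path | None = None,
    resample_step: float = 2.0,
    refined_out: dict | None = None,
) -> pd.DataFrame:
    """Run each method over the dataset and tabulate all metrics.

    The unrefined input ("identity") row is always included as the
    pre-refinement baseline. Writes ``metrics.csv`` and ``summary.json``
    (per-method means, post/pre deviation ratios in %, failure counts) when
    ``out_path`` is given. Failed sample×method runs are flagged and excluded
    from the aggregates.
    """
    registry = _method_registry()
    unknown = [m for m in methods if m not in registry]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; known: {sorted(registry)}")
    if "identity" not in methods:
        methods = ["identity", *methods]
    records: list[MetricsRecord] = []
    for sid, sample in enumerate(dataset):
        for m in methods:
            try:
                refined = registry[m](sample)
                if refined_out is not None:
                    refined_out[(sid, m)] = refined
                records.append(evaluate_tree(sample, refined, m, sid, resample_step))
            except Exception:  # noqa: BLE001 - a failing method must not kill the run
                log.exception("method %s failed on sample %d", m, sid)
                records.append(
                    MetricsRecord(sid, m, sample.case_label, *([float("nan")] * 5), 0, 0, failed=True)
                )
    df = pd.DataFrame([asdict(r) for r in records])
    if out_path is not None:
        out = Path(out_path)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "metrics.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summarize(df), indent=1, sort_keys=True))
    return df


def summarize(df: pd.DataFrame) -> dict:
    """Aggregate means per method plus post/pre deviation ratios (% of the
    unrefined baseline, ratio of the global means) and per-block ratios."""
    ok = df[~df.failed]
    base = ok[ok.method == "identity"]
    metrics = [
        "skeleton_deviation",
        "bifurcation_deviation",
        "radius_mae",
        "intensity_mean",
        "info_extraction_rate",
        "node_count",
        "file_bytes",
    ]
    summary: dict = {"n_samples": int(df.sample_id.nunique()), "methods": {}}
    for m in ok.method.unique():
        sub = ok[ok.method == m]
        entry = {k: float(np.nanmean(sub[k])) for k in metrics}
        entry["information_loss_pct"] = 100.0 * (1.0 - entry["info_extraction_rate"])
        entry["n_failed"] = int(df[(df.method == m) & df.failed].shape[0])
        for k in ("skeleton_deviation", "bifurcation_deviation"):
            b = float(np.nanmean(base[k]))
            if b > 0:
                entry[f"{k}_ratio_pct"] = 100.0 * entry[k] / b
                merged = sub.merge(base[["sample_id", k]], on="sample_id", suffixes=("", "_pre"))
                pre = merged[f"{k}_pre"].to_numpy(float)
                post = merged[k].to_numpy(float)
                mask = pre > 0
                entry[f"{k}_ratio_pct_per_block_mean"] = (
                    float(np.nanmean(100.0 * post[mask] / pre[mask])) if mask.any() else float("nan")
                )
        summary["methods"][m] = entry
    return summary
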