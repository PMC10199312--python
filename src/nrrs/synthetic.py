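"""Synthetic benchmark generator: ground-truth skeletons, perturbed copies and
rendered tube images.

Each sample is a triplet (ground-truth tree, perturbed "test" tree, 3D image
block). The skeleton is a smooth cubic Bézier tube spanning the block (with an
optional Bézier side branch), the image is a Gaussian-profile tube plus
Gaussian noise quantized to 8 bits, and the perturbation reproduces one of
three deviation patterns seen in practice:

* ``case1_bend`` — a bent stretch is replaced by its straight chord (the
  reconstruction misses a bend of the signal);
* ``case2_bifurcation`` — the branching point is displaced and the offset is
  blended into the adjacent nodes (mis-placed bifurcation);
* ``case3_shift`` — the whole neurite drifts by 3–8 voxels except at the soma
  and terminals, which are assumed correct.

Everything is a pure function of its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .swc_core import (
    NeuronTree,
    SwcNode,
    polyline_arc_length,
    resample_polyline,
    write_swc,
)
from .gd_tracer import ImageBlock

__all__ = [
    "TubeModel",
    "SyntheticSample",
    "CASE_LABELS",
    "generate_skeleton",
    "render_image",
    "perturb",
    "generate_dataset",
    "max_turning_angle",
]

CASE_LABELS = ("case1_bend", "case2_bifurcation", "case3_shift")

DEFAULT_BLOCK_SHAPE = (128, 128, 64)


@dataclass
class TubeModel:
    """Image-formation model of one neurite tube.

    ``radius`` is the half-amplitude radius of the Gaussian cross profile
    (``profile_sigma = radius / sqrt(2 ln 2)``, set automatically when left
    at 0), so the rendered tube reaches half its amplitude exactly at the
    stored SWC radius.
    """

    radius: float = 2.0  # voxels
    peak_intensity: float = 200.0
    profile_sigma: float = 0.0  # voxels; 0 -> derived from radius
    background_level: float = 12.0
    noise_sigma: float = 6.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.peak_intensity <= self.background_level:
            raise ValueError("peak_intensity must exceed background_level")
        if self.profile_sigma <= 0:
            self.profile_sigma = self.radius / np.sqrt(2.0 * np.log(2.0))


@dataclass
class SyntheticSample:
    ground_truth: NeuronTree
    perturbed: NeuronTree
    image: ImageBlock
    case_label: str
    gen_params: dict = field(default_factory=dict)


# -- skeleton formation ----------------------------------------------------


def _bezier(p0, p1, p2, p3, t):
    t = t[:, None]
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * p1
        + 3 * (1 - t) * t**2 * p2
        + t**3 * p3
    )


def _sample_bezier_unit_steps(ctrl: np.ndarray) -> np.ndarray:
    """Sample a cubic Bézier at ~1-voxel arc steps."""
    t = np.linspace(0, 1, 600)
    dense = _bezier(*ctrl, t)
    length = polyline_arc_length(dense)
    n = max(int(round(length)), 2)
    return resample_polyline(dense, length / n)


def max_turning_angle(points: np.ndarray, window: int = 10) -> float:
    """Largest direction change (degrees) between successive chords of
    ``window`` samples — the bend-strength measure used by the generator."""
    points = np.asarray(points, float)
    if len(points) < 2 * window + 1:
        window = max(1, (len(points) - 1) // 2)
    best = 0.0
    for i in range(window, len(points) - window):
        a = points[i] - points[i - window]
        b = points[i + window] - points[i]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            continue
        cosv = np.clip(np.dot(a, b) / (na * nb), -1, 1)
        best = max(best, np.degrees(np.arccos(cosv)))
    return best


def _tree_from_polylines(main: np.ndarray, branch: np.ndarray | None,
                         attach_idx: int | None, radius: float) -> NeuronTree:
    nodes = [
        SwcNode(i + 1, 1 if i == 0 else 3, main[i], radius, -1 if i == 0 else i)
        for i in range(len(main))
    ]
    if branch is not None:
        base = len(nodes)
        parent = attach_idx + 1
        for j in range(len(branch)):
            nodes.append(
                SwcNode(base + j + 1, 3, branch[j], radius,
                        parent if j == 0 else base + j)
            )
    tree = NeuronTree(nodes)
    tree.validate()
    return tree


def generate_skeleton(
    seed: int,
    block_shape: Sequence[int] = DEFAULT_BLOCK_SHAPE,
    with_bifurcation: bool = True,
    radius: float = 2.0,
    min_turning_deg: float = 35.0,
) -> NeuronTree:
    """Random smooth skeleton spanning the block's z extent.

    A cubic Bézier with laterally offset interior control points runs from a
    region near the low-z face to one near the high-z face, sampled at
    1-voxel arc steps; draws are repeated until the strongest bend reaches
    ``min_turning_deg``. With ``with_bifurcation`` a second Bézier branch
    leaves a random mid-arc node at 30–90 degrees. All points keep a margin
    of at least twice the tube radius from the block border.
    """
    shape = np.asarray(block_shape, int)
    if np.any(shape < 32):
        raise ValueError("block_shape must be >= 32 voxels per axis")
    rng = np.random.default_rng(seed)
    margin = max(6.0, 2.0 * radius + 1.0)
    lo = np.full(3, margin)
    hi = shape - 1 - margin

    def lateral_point(z: float) -> np.ndarray:
        c = (lo + hi) / 2
        span = (hi - lo) * 0.3
        return np.array(
            [rng.uniform(c[0] - span[0], c[0] + span[0]),
             rng.uniform(c[1] - span[1], c[1] + span[1]), z]
        )

    for _ in range(60):
        p0 = lateral_point(lo[2])
        p3 = lateral_point(hi[2])
        # opposite lateral offsets on the interior control points make an S/U bend
        theta = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(22, 42)
        off = np.array([np.cos(theta), np.sin(theta), 0.0]) * amp
        p1 = p0 + (p3 - p0) * rng.uniform(0.25, 0.4) + off
        p2 = p0 + (p3 - p0) * rng.uniform(0.6, 0.75) - off * rng.uniform(0.6, 1.2)
        ctrl = np.clip(np.array([p0, p1, p2, p3]), lo, hi)
        main = _sample_bezier_unit_steps(ctrl)
        if max_turning_angle(main) < min_turning_deg:
            continue
        branch = None
        attach_idx = None
        if with_bifurcation:
            branch, attach_idx = _grow_branch(rng, main, lo, hi)
            if branch is None:
                continue
        return _tree_from_polylines(main, branch, attach_idx, radius)
    raise RuntimeError("could not generate a skeleton satisfying the bend constraint")


def _grow_branch(rng, main, lo, hi):
    """Second Bézier leaving a mid-arc node of the main path at 30–90 deg."""
    for _ in range(40):
        attach_idx = int(rng.integers(int(len(main) * 0.3), int(len(main) * 0.7)))
        a = main[attach_idx]
        tangent = main[min(attach_idx + 3, len(main) - 1)] - main[max(attach_idx - 3, 0)]
        tangent = tangent / np.linalg.norm(tangent)
        # random direction at 30-90 degrees from the local tangent
        ang = np.radians(rng.uniform(30, 90))
        perp = rng.normal(size=3)
        perp -= np.dot(perp, tangent) * tangent
        nperp = np.linalg.norm(perp)
        if nperp < 1e-9:
            continue
        perp /= nperp
        direction = np.cos(ang) * tangent + np.sin(ang) * perp
        length = rng.uniform(22, 38)
        end = a + direction * length
        if np.any(end < lo) or np.any(end > hi):
            continue
        c1 = a + direction * length * 0.35 + rng.normal(scale=2.0, size=3)
        c2 = a + direction * length * 0.7 + rng.normal(scale=3.0, size=3)
        ctrl = np.clip(np.array([a, c1, c2, end]), lo, hi)
        pts = _sample_bezier_unit_steps(ctrl)
        return pts[1:], attach_idx  # drop the shared attach point
    return None, None


# -- image formation -------------------------------------------------------


def _tree_branch_polylines(tree: NeuronTree) -> list[np.ndarray]:
    from .swc_core import decompose_branches

    return [b.node_positions for b in decompose_branches(tree)]


def render_image(
    tree: NeuronTree,
    block_shape: Sequence[int] = DEFAULT_BLOCK_SHAPE,
    tube: TubeModel | None = None,
    seed: int = 0,
) -> ImageBlock:
    """Render the skeleton as a Gaussian-profile tube with additive noise.

    Noise-free intensity at voxel v is
    ``background + (peak-background) * exp(-d(v)^2 / (2 sigma^2))`` with d(v)
    the distance from v to the skeleton (computed against a dense 0.25-voxel
    resampling, so the discretization error is negligible); Gaussian noise is
    added, clipped at zero and quantized to 8 bits.
    """
    tube = tube or TubeModel()
    shape = tuple(int(s) for s in block_shape)
    rng = np.random.default_rng(seed)
    dense = np.vstack([
        resample_polyline(poly, 0.25) if polyline_arc_length(poly) > 0.25 else poly
        for poly in _tree_branch_polylines(tree)
    ]) if len(tree) > 1 else tree.positions()
    kd = cKDTree(dense)
    cutoff = tube.profile_sigma * 3.5 + 1.0
    lo = np.maximum(np.floor(dense.min(axis=0) - cutoff).astype(int), 0)
    hi = np.minimum(np.ceil(dense.max(axis=0) + cutoff).astype(int), np.array(shape) - 1)
    img = np.full(shape, tube.background_level, dtype=float)
    ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1).astype(float)
    d, _ = kd.query(pts)
    amp = tube.peak_intensity - tube.background_level
    vals = tube.background_level + amp * np.exp(-(d**2) / (2 * tube.profile_sigma**2))
    img[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = vals.reshape(gx.shape)
    if tube.noise_sigma > 0:
        img = img + rng.normal(scale=tube.noise_sigma, size=shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImageBlock(img)


# -- perturbations ---------------------------------------------------------


def _main_branch_interior(tree: NeuronTree):
    """Indices (into tree.nodes) of the longest branch's interior nodes."""
    from .swc_core import decompose_branches

    branches = decompose_branches(tree)
    lengths = [polyline_arc_length(b.node_positions) for b in branches]
    b = branches[int(np.argmax(lengths))]
    return b


def _case1_bend(tree: NeuronTree, rng) -> NeuronTree:
    """Replace the most-bent interior window of the longest branch by its
    straight chord; the window starts at ~20 nodes and grows (<=45) until the
    shortcut leaves a clearly measurable skeleton deviation."""
    out = tree.copy()
    branch = _main_branch_interior(out)
    pts = branch.node_positions
    ids = branch.node_ids
    n = len(pts)
    # most-bent center: max turning point of the branch
    best_i, best_a = n // 2, -1.0
    w = 8
    for i in range(w, n - w):
        a = pts[i] - pts[i - w]
        b = pts[i + w] - pts[i]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            continue
        ang = np.degrees(np.arccos(np.clip(np.dot(a, b) / (na * nb), -1, 1)))
        if ang > best_a:
            best_a, best_i = ang, i
    from .evaluation import skeleton_deviation

    cand = out
    for half in range(10, 24, 3):
        a = max(1, best_i - half)
        b = min(n - 2, best_i + half)
        if b - a < 3:
            continue
        cand = out.copy()
        chord = np.linspace(pts[a], pts[b], b - a + 1)
        for j, idx in enumerate(range(a, b + 1)):
            cand.node(ids[idx]).position = chord[j].copy()
        if skeleton_deviation(cand, tree) > 1.05:
            return cand
    return cand  # largest window; generate_dataset re-draws if still too mild


def _taper_weights(dist_to_end: np.ndarray, taper: int) -> np.ndarray:
    return np.clip(dist_to_end / float(taper), 0.0, 1.0)


def _case2_bifurcation(tree: NeuronTree, rng, magnitude: float) -> NeuronTree:
    """Displace one bifurcation by ``magnitude`` and blend the displacement
    linearly into the ~10 nearest nodes of each incident branch; the root,
    tips and other critical nodes stay fixed."""
    out = tree.copy()
    bifs = out.bifurcations()
    if not bifs:
        raise ValueError("case2 perturbation needs a bifurcation")
    bif = bifs[int(rng.integers(len(bifs)))]
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    disp = direction * magnitude
    cm = out.children_map()
    root_id = out.root.id
    blend = 10
    out.node(bif.id).position = out.node(bif.id).position + disp

    chains: list[list[int]] = []
    # upstream chain toward the root
    chain: list[int] = []
    cur = out.node(bif.id).parent_id
    while (
        cur != -1 and cur != root_id and len(cm[cur]) == 1 and len(chain) < blend - 1
    ):
        chain.append(cur)
        cur = out.node(cur).parent_id
    chains.append(chain)
    # downstream chains along each child branch
    for child in cm[bif.id]:
        chain = []
        cur = child
        while len(cm[cur]) == 1 and len(chain) < blend - 1:
            chain.append(cur)
            cur = cm[cur][0]
        chains.append(chain)
    for chain in chains:
        for step, nid in enumerate(chain, start=1):
            out.node(nid).position = out.node(nid).position + disp * (1.0 - step / blend)
    return out


def _case3_shift(tree: NeuronTree, rng, magnitude: float) -> NeuronTree:
    """Shift every interior node by one random direction of length
    ``magnitude``, tapering to zero over the 5 nodes nearest the root and
    each tip (those endpoints are assumed correct and stay fixed)."""
    out = tree.copy()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    disp = direction * magnitude
    cm = out.children_map()
    root_id = out.root.id
    tip_ids = {t.id for t in out.tips()}
    # graph distance (in nodes) to the nearest fixed endpoint
    adj: dict[int, list[int]] = {n.id: list(cm[n.id]) for n in out.nodes}
    for n in out.nodes:
        if n.parent_id != -1:
            adj[n.id].append(n.parent_id)
    from collections import deque

    dist = {nid: np.inf for nid in adj}
    dq = deque()
    for e in tip_ids | {root_id}:
        dist[e] = 0
        dq.append(e)
    while dq:
        cur = dq.popleft()
        for nb in adj[cur]:
            if dist[nb] > dist[cur] + 1:
                dist[nb] = dist[cur] + 1
                dq.append(nb)
    taper = 5
    for n in out.nodes:
        w = min(dist[n.id], taper) / taper
        if w > 0:
            n.position = n.position + disp * w
    return out


def perturb(
    tree: NeuronTree, case_label: str, seed: int, magnitude: float = 5.0
) -> NeuronTree:
    """Apply one deviation case to a copy of ``tree``; topology, root and tip
    positions are preserved in every case."""
    rng = np.random.default_rng(seed)
    if case_label == "case1_bend":
        out = _case1_bend(tree, rng)
    elif case_label == "case2_bifurcation":
        out = _case2_bifurcation(tree, rng, magnitude)
    elif case_label == "case3_shift":
        out = _case3_shift(tree, rng, magnitude)
    else:
        raise ValueError(f"unknown case label {case_label!r}; expected one of {CASE_LABELS}")
    out.validate()
    return out


# -- dataset driver --------------------------------------------------------


def _sample_invariants_ok(sample: SyntheticSample) -> bool:
    from .evaluation import skeleton_deviation

    gt, pert = sample.ground_truth, sample.perturbed
    if len(gt) != len(pert):
        return False
    if not np.allclose(gt.root.position, pert.root.position):
        return False
    for a, b in zip(gt.tips(), pert.tips()):
        if not np.allclose(a.position, b.position):
            return False
    return skeleton_deviation(pert, gt) > 1.0


def generate_dataset(
    n: int,
    seed: int,
    case_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    block_shape: Sequence[int] = DEFAULT_BLOCK_SHAPE,
    tube: TubeModel | None = None,
    out_dir: str | Path | None = None,
) -> list[SyntheticSample]:
    """Generate ``n`` samples with case labels in the given proportions.

    Per-sample seeds derive from the master seed; a draw violating the sample
    invariants (fixed endpoints, topology, measurable deviation) is redrawn
    from the next derived seed. With ``out_dir`` each sample is serialized as
    ``sample_XXXX/{gt.swc,test.swc,image.tif,params.json}``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    case_mix = np.asarray(case_mix, float)
    if abs(case_mix.sum() - 1.0) > 1e-9:
        raise ValueError("case_mix proportions must sum to 1")
    counts = np.floor(case_mix * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmin(counts / np.maximum(case_mix, 1e-12)))] += 1
    labels = [lab for lab, c in zip(CASE_LABELS, counts) for _ in range(c)]
    master = np.random.default_rng(seed)
    samples: list[SyntheticSample] = []
    for i, label in enumerate(labels):
        for attempt in range(50):
            sub = int(master.integers(0, 2**31 - 1))
            sample = _make_sample(sub, label, block_shape, tube)
            if _sample_invariants_ok(sample):
                break
        else:
            raise RuntimeError(f"could not generate a valid sample for {label}")
        sample.gen_params["index"] = i
        samples.append(sample)
    if out_dir is not None:
        _serialize(samples, Path(out_dir))
    return samples


def _make_sample(sub_seed: int, label: str, block_shape, tube: TubeModel | None) -> SyntheticSample:
    rng = np.random.default_rng(sub_seed)
    radius = float(rng.uniform(2.0, 2.75))
    tube = tube or TubeModel(radius=radius)
    gt = generate_skeleton(int(rng.integers(2**31 - 1)), block_shape,
                           with_bifurcation=True, radius=tube.radius)
    if label == "case2_bifurcation":
        magnitude = float(rng.uniform(8.0, 12.0))
    elif label == "case3_shift":
        magnitude = float(rng.uniform(3.0, 8.0))
    else:
        magnitude = 0.0
    pert = perturb(gt, label, int(rng.integers(2**31 - 1)), magnitude)
    img = render_image(gt, block_shape, tube, seed=int(rng.integers(2**31 - 1)))
    params = {
        "seed": sub_seed,
        "case_label": label,
        "magnitude": magnitude,
        "block_shape": [int(s) for s in block_shape],
        "tube": asdict(tube),
    }
    return SyntheticSample(gt, pert, img, label, params)


def _serialize(samples: list[SyntheticSample], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        d = out_dir / f"sample_{i:04d}"
        d.mkdir(exist_ok=True)
        write_swc(s.ground_truth, d / "gt.swc")
        write_swc(s.perturbed, d / "test.swc")
        s.image.to_tiff(d / "image.tif")
        (d / "params.json").write_text(json.dumps(s.gen_params, indent=1, sort_keys=True))


def load_dataset(in_dir: str | Path) -> list[SyntheticSample]:
    """Load a serialized dataset written by :func:`generate_dataset`."""
    from .swc_core import read_swc

    samples = []
    for d in sorted(Path(in_dir).glob("sample_*")):
        params = json.loads((d / "params.json").read_text())
        samples.append(
            SyntheticSample(
                read_swc(d / "gt.swc"),
                read_swc(d / "test.swc"),
                ImageBlock.from_tiff(d / "image.tif"),
                params["case_label"],
                params,
            )
        )
    return samples
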