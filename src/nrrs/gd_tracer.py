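"""Graph-augmented deformable (GD) two-point tracer.

The tracer refines a path between two given endpoints in a 3D image block in
two phases:

1. *graph step* — Dijkstra shortest path on the 26-connected voxel graph with
   intensity-derived edge weights ``e(v0,v1) = ||v0-v1|| * (gI(v0)+gI(v1))/2``
   where ``gI(v) = exp(lambda_I * (1 - I(v)/Imax)^2)``, so bright voxels are
   cheap and dark voxels exponentially expensive;
2. *deform step* — local energy minimization of the resulting control-point
   curve under ``E = alpha*E_image + beta*E_length + gamma*E_smoothness``,
   pulling interior points to the local intensity centroid (sub-voxel) while
   keeping the curve short and smooth. Endpoints stay fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

log = logging.getLogger(__name__)

__all__ = [
    "ImageBlock",
    "Curve",
    "EnergyParams",
    "BlockSizeError",
    "intensity_metric",
    "edge_weight",
    "graph_shortest_path",
    "energy_length",
    "energy_smoothness",
    "energy_image",
    "total_energy",
    "deform",
    "trace",
]

# voxel budget above which the graph step refuses to build (512*512*256,
# the size of the whole-brain sampling blocks this tool targets)
DEFAULT_MAX_GRAPH_VOXELS = 512 * 512 * 256


class BlockSizeError(ValueError):
    """Block exceeds the graph-step voxel budget; crop before tracing."""


@dataclass
class ImageBlock:
    """A 3D intensity grid with its offset into the parent volume.

    ``data`` is indexed ``[x, y, z]`` to match SWC coordinate order; the
    multi-page-TIFF page axis (z) is transposed on load.
    """

    data: np.ndarray  # (nx, ny, nz), non-negative
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("image block must be 3D")
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def imax(self) -> float:
        return float(self.data.max())

    @classmethod
    def from_tiff(cls, path, voxel_size=(1, 1, 1)) -> "ImageBlock":
        import tifffile

        pages = tifffile.imread(path)  # (z, y, x)
        if pages.ndim == 2:
            pages = pages[None]
        return cls(np.ascontiguousarray(pages.T), voxel_size=np.asarray(voxel_size, float))

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, np.ascontiguousarray(self.data.T))

    def interp(self, points: np.ndarray) -> np.ndarray:
        """Trilinear intensity at continuous voxel coordinates (clipped)."""
        return trilinear(self.data, np.atleast_2d(points))


@dataclass
class Curve:
    """Control-point sequence being optimized; endpoints are fixed."""

    control_points: np.ndarray  # (K, 3) continuous voxel coords

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or len(self.control_points) < 2:
            raise ValueError("a curve needs at least 2 control points")

    def __len__(self) -> int:
        return len(self.control_points)


@dataclass
class EnergyParams:
    """Coefficients and numerical knobs of the deformable model.

    alpha/beta/gamma weigh image fit, length and smoothness (Eq. style
    ``E = a*E_img + b*E_len + c*E_smooth``); ``lambda_I`` sharpens the
    intensity metric, ``lambda_C`` scales the centroid-distance term and
    ``neighborhood_radius`` (voxels) bounds the local window used for both.
    """

    alpha: float = 1.0
    beta: float = 0.2
    gamma: float = 0.2
    lambda_I: float = 10.0
    lambda_C: float = 1.0
    neighborhood_radius: float = 4.0
    max_deform_iters: int = 100
    energy_tol: float = 1e-4
    step_size: float = 0.5
    max_graph_voxels: int = DEFAULT_MAX_GRAPH_VOXELS

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("energy coefficients must be non-negative")
        if self.alpha + self.beta + self.gamma <= 0:
            raise ValueError("alpha+beta+gamma must be positive")
        if self.lambda_I <= 0 or self.lambda_C <= 0:
            raise ValueError("lambda_I and lambda_C must be positive")
        if self.neighborhood_radius <= 0:
            raise ValueError("neighborhood_radius must be positive")


# -- low-level numerics ----------------------------------------------------


def trilinear(data: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``data[x,y,z]`` at continuous points."""
    pts = np.asarray(pts, dtype=float)
    shape = np.array(data.shape)
    p = np.clip(pts, 0, shape - 1.000001)
    i0 = np.floor(p).astype(int)
    f = p - i0
    out = np.zeros(len(p))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                out += w * data[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def intensity_metric(i_v: float | np.ndarray, imax: float, lambda_i: float) -> np.ndarray:
    """Intensity cost ``gI = exp(lambda_I * (1 - I/Imax)^2)``; 1 at Imax,
    ``exp(lambda_I)`` in darkness; strictly decreasing in intensity."""
    if imax <= 0:
        raise ValueError("degenerate block: Imax must be positive")
    return np.exp(lambda_i * (1.0 - np.asarray(i_v, dtype=float) / imax) ** 2)


_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
)


def edge_weight(v0, v1, block: ImageBlock, lambda_i: float = 10.0) -> float:
    """Weight of one 26-neighborhood edge: physical length times the mean
    intensity cost of its two endpoint voxels."""
    v0 = np.asarray(v0, int)
    v1 = np.asarray(v1, int)
    d = v1 - v0
    if np.max(np.abs(d)) != 1:
        raise ValueError("voxels are not 26-neighbors")
    imax = block.imax
    g0 = intensity_metric(block.data[tuple(v0)], imax, lambda_i)
    g1 = intensity_metric(block.data[tuple(v1)], imax, lambda_i)
    length = float(np.linalg.norm(d * block.voxel_size))
    return length * float(g0 + g1) / 2.0


def _build_graph(block: ImageBlock, lambda_i: float):
    """Sparse 26-connected voxel graph with Eq.-style weights (vectorized)."""
    nx, ny, nz = block.shape
    n = nx * ny * nz
    g = intensity_metric(block.data.astype(float), block.imax, lambda_i)
    idx = np.arange(n).reshape(block.shape)
    rows, cols, ws = [], [], []
    vs = block.voxel_size
    for off in _NEIGHBOR_OFFSETS:
        # undirected graph: emit each edge once
        if tuple(off) > tuple(-off):
            continue
        sl_src = tuple(slice(max(0, -o), min(s, s - o)) for o, s in zip(off, block.shape))
        sl_dst = tuple(slice(max(0, o), min(s, s + o)) for o, s in zip(off, block.shape))
        length = float(np.linalg.norm(off * vs))
        w = length * 0.5 * (g[sl_src] + g[sl_dst])
        rows.append(idx[sl_src].ravel())
        cols.append(idx[sl_dst].ravel())
        ws.append(w.ravel())
    return coo_matrix(
        (np.concatenate(ws), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()


def graph_shortest_path(
    block: ImageBlock, start, end, lambda_i: float = 10.0, max_voxels: int | None = None
) -> Curve:
    """Dijkstra minimum-weight 26-connected voxel path from start to end.

    ``start``/``end`` are integer voxel coordinates inside the block. Raises
    :class:`BlockSizeError` for blocks above the voxel budget (crop first).
    """
    budget = DEFAULT_MAX_GRAPH_VOXELS if max_voxels is None else max_voxels
    if np.prod(block.shape) > budget:
        raise BlockSizeError(
            f"block of {block.shape} exceeds the {budget}-voxel graph budget; crop it"
        )
    start = np.asarray(start, int)
    end = np.asarray(end, int)
    shape = block.shape
    for p in (start, end):
        if np.any(p < 0) or np.any(p >= shape):
            raise ValueError(f"point {p} outside block of shape {shape}")
    if np.array_equal(start, end):
        raise ValueError("start and end voxels coincide")
    graph = _build_graph(block, lambda_i)
    i0 = int(np.ravel_multi_index(start, shape))
    i1 = int(np.ravel_multi_index(end, shape))
    dist, pred = _sp_dijkstra(
        graph, directed=False, indices=i0, return_predecessors=True
    )
    if not np.isfinite(dist[i1]):
        raise RuntimeError("end voxel unreachable")  # impossible on a full grid
    chain = [i1]
    while chain[-1] != i0:
        chain.append(int(pred[chain[-1]]))
    path = np.array(np.unravel_index(chain[::-1], shape)).T.astype(float)
    return Curve(path)


# -- energy terms ----------------------------------------------------------


def energy_length(curve: Curve) -> float:
    """Sum of squared gaps between consecutive control points."""
    d = np.diff(curve.control_points, axis=0)
    return float(np.sum(d * d))


def energy_smoothness(curve: Curve) -> float:
    """Sum over interior points of the squared offset from the midpoint of
    their neighbors; zero iff the curve is equally spaced and collinear."""
    c = curve.control_points
    if len(c) < 3:
        return 0.0
    mid = 0.5 * (c[:-2] + c[2:])
    d = c[1:-1] - mid
    return float(np.sum(d * d))


def _neighborhood(block: ImageBlock, p: np.ndarray, r: float):
    """Voxel centers within Euclidean distance r of p, clipped to the block.

    Returns (coords (m,3) int, intensities (m,), squared distances (m,)).
    """
    shape = np.array(block.shape)
    lo = np.maximum(np.ceil(p - r).astype(int), 0)
    hi = np.minimum(np.floor(p + r).astype(int), shape - 1)
    if np.any(lo > hi):
        return None
    ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    q = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    diff = q - p
    d2 = np.sum(diff * diff, axis=1)
    mask = d2 <= r * r
    if not mask.any():
        return None
    q = q[mask]
    return q, block.data[q[:, 0], q[:, 1], q[:, 2]].astype(float), d2[mask]


def _point_image_energy(block: ImageBlock, p: np.ndarray, params: EnergyParams) -> float:
    """EI + EC at one control point; a fully dark neighborhood contributes
    the fallback value lambda_I (logged by the caller once per curve)."""
    nb = _neighborhood(block, p, params.neighborhood_radius)
    if nb is None:
        return params.lambda_I
    q, inten, d2 = nb
    tot = inten.sum()
    if tot <= 0:
        return params.lambda_I
    local_max = inten.max()
    ic = float(trilinear(block.data, p[None])[0])
    ei = params.lambda_I * (1.0 - min(ic, local_max) / local_max) ** 2
    ec = params.lambda_C * float(np.dot(d2, inten)) / float(tot)
    return ei + ec


def energy_image(curve: Curve, block: ImageBlock, params: EnergyParams) -> float:
    """Image energy: per control point, the intensity shortfall against the
    local maximum (EI) plus the intensity-weighted squared distance to the
    neighborhood centroid spread (EC)."""
    return float(
        sum(_point_image_energy(block, p, params) for p in curve.control_points)
    )


def total_energy(curve: Curve, block: ImageBlock, params: EnergyParams) -> float:
    return (
        params.alpha * energy_image(curve, block, params)
        + params.beta * energy_length(curve)
        + params.gamma * energy_smoothness(curve)
    )


# -- deform step -----------------------------------------------------------


def _intensity_centroid(block: ImageBlock, p: np.ndarray, r: float):
    nb = _neighborhood(block, p, r)
    if nb is None:
        return None
    q, inten, _ = nb
    tot = inten.sum()
    if tot <= 0:
        return None
    return (q * inten[:, None]).sum(axis=0) / tot


def _local_energy(c: np.ndarray, k: int, p: np.ndarray, block, params) -> float:
    """Terms of the total energy that involve control point k placed at p."""
    e = params.alpha * _point_image_energy(block, p, params)
    e += params.beta * float(np.sum((p - c[k - 1]) ** 2) + np.sum((c[k + 1] - p) ** 2))
    if params.gamma > 0:
        e += params.gamma * float(np.sum((p - 0.5 * (c[k - 1] + c[k + 1])) ** 2))
        if k - 1 >= 1:
            e += params.gamma * float(np.sum((c[k - 1] - 0.5 * (c[k - 2] + p)) ** 2))
        if k + 1 <= len(c) - 2:
            e += params.gamma * float(np.sum((c[k + 1] - 0.5 * (p + c[k + 2])) ** 2))
    return e


def deform(
    curve: Curve,
    block: ImageBlock,
    params: EnergyParams,
    return_history: bool = False,
):
    """Energy-minimizing refinement of a curve with fixed endpoints.

    Cyclic coordinate-wise scheme: each interior point takes a damped step
    toward a blend of the local intensity centroid (image term) and its
    neighbors' midpoint (length + smoothness terms); a move is kept only if
    it lowers the energy, so the total energy is non-increasing. Stops when
    the per-sweep energy change drops below ``energy_tol`` or after
    ``max_deform_iters`` sweeps.
    """
    c = curve.control_points.copy()
    K = len(c)
    history = [total_energy(Curve(c), block, params)]
    if K <= 2:
        return (Curve(c), history) if return_history else Curve(c)
    bounds_hi = np.array(block.shape) - 1.0
    r = params.neighborhood_radius
    w_geom = params.beta + params.gamma
    dark_warned = False
    for _ in range(params.max_deform_iters):
        for k in range(1, K - 1):
            t_geom = 0.5 * (c[k - 1] + c[k + 1])
            t_img = _intensity_centroid(block, c[k], r) if params.alpha > 0 else None
            if t_img is None:
                if params.alpha > 0 and not dark_warned:
                    log.debug("all-dark neighborhood during deform; geometric update only")
                    dark_warned = True
                w_i = 0.0
                t_img = c[k]
            else:
                w_i = params.alpha
            if w_i + w_geom <= 0:
                continue
            target = (w_i * t_img + w_geom * t_geom) / (w_i + w_geom)
            cand = c[k] + params.step_size * (target - c[k])
            cand = np.clip(cand, 0.0, bounds_hi)
            if _local_energy(c, k, cand, block, params) < _local_energy(
                c, k, c[k], block, params
            ):
                c[k] = cand
        e = total_energy(Curve(c), block, params)
        history.append(e)
        if abs(history[-2] - e) < params.energy_tol:
            break
    else:
        log.debug("deform hit max_deform_iters without convergence")
    out = Curve(c)
    return (out, history) if return_history else out


def trace(block: ImageBlock, p0, p1, params: EnergyParams | None = None) -> Curve:
    """Two-point GD trace: Dijkstra between the rounded endpoints, then the
    deform step; the exact (possibly sub-voxel) endpoints are restored."""
    params = params or EnergyParams()
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    hi = np.array(block.shape) - 1
    v0 = np.clip(np.round(p0).astype(int), 0, hi)
    v1 = np.clip(np.round(p1).astype(int), 0, hi)
    if np.array_equal(v0, v1):
        log.warning("trace called with (nearly) coincident endpoints")
        return Curve(np.vstack([p0, p1 + (0 if np.any(p0 != p1) else 1e-6)]))
    path = graph_shortest_path(block, v0, v1, params.lambda_I, params.max_graph_voxels)
    refined = deform(path, block, params)
    pts = refined.control_points
    pts[0] = p0
    pts[-1] = p1
    return Curve(pts)
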