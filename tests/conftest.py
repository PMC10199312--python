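"""Shared fixtures: small hand-built trees and analytic tube phantoms.

The tube phantoms are computed from exact point-to-segment distances, so
tracer tests do not depend on the package's own renderer.
"""

from __future__ import annotations

import numpy as np
import pytest

from nrrs.gd_tracer import ImageBlock
from nrrs.swc_core import NeuronTree, SwcNode


def tree_from_rows(rows) -> NeuronTree:
    """rows: (id, type, x, y, z, radius, parent)"""
    return NeuronTree(
        [SwcNode(r[0], r[1], np.array(r[2:5], float), r[5], r[6]) for r in rows]
    )


@pytest.fixture
def y_tree() -> NeuronTree:
    """Root - stem - bifurcation - two tips."""
    return tree_from_rows(
        [
            (1, 1, 0, 0, 0, 1.0, -1),
            (2, 3, 0, 5, 0, 1.0, 1),
            (3, 3, 0, 10, 0, 1.0, 2),
            (4, 3, -4, 14, 0, 1.0, 3),
            (5, 3, 4, 14, 0, 1.0, 3),
        ]
    )


@pytest.fixture
def chain_tree() -> NeuronTree:
    rows = [(1, 1, 0, 0, 0, 1.0, -1)] + [
        (i, 3, 0.0, float(i - 1) * 2, 0.0, 1.0, i - 1) for i in range(2, 11)
    ]
    return tree_from_rows(rows)


def segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact distance from points to segment a-b."""
    ab = b - a
    t = np.clip((points - a) @ ab / max(ab @ ab, 1e-24), 0, 1)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def make_tube(
    shape=(40, 16, 16),
    p0=(4, 8, 8),
    p1=(36, 8, 8),
    sigma: float = 2.0,
    peak: float = 200.0,
    background: float = 0.0,
) -> ImageBlock:
    """Analytic Gaussian tube between two points (noise-free, float data)."""
    ax = [np.arange(s, dtype=float) for s in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d = segment_distance(pts, np.asarray(p0, float), np.asarray(p1, float))
    data = background + (peak - background) * np.exp(-(d**2) / (2 * sigma**2))
    return ImageBlock(data.reshape(shape))


def make_l_tube(shape=(32, 32, 12), corner=(24, 24, 6), start=(4, 24, 6), end=(24, 4, 6),
                sigma=2.0, peak=200.0) -> ImageBlock:
    """Analytic L-bent tube: two joined straight limbs."""
    ax = [np.arange(s, dtype=float) for s in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d1 = segment_distance(pts, np.asarray(start, float), np.asarray(corner, float))
    d2 = segment_distance(pts, np.asarray(corner, float), np.asarray(end, float))
    d = np.minimum(d1, d2)
    data = peak * np.exp(-(d**2) / (2 * sigma**2))
    return ImageBlock(data.reshape(shape))


def random_tree(rng: np.random.Generator, n_branches: int = 4, step: float = 1.0) -> NeuronTree:
    """Random branching tree with ~unit node spacing (for property tests)."""
    nodes = [SwcNode(1, 1, rng.uniform(10, 20, 3), 1.0, -1)]
    next_id = 2
    open_ends = [1]
    for _ in range(n_branches):
        src = int(rng.choice(open_ends))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        n_nodes = int(rng.integers(4, 15))
        prev = src
        for _ in range(n_nodes):
            direction += rng.normal(scale=0.2, size=3)
            direction /= np.linalg.norm(direction)
            pos = nodes[prev - 1].position + direction * step
            nodes.append(SwcNode(next_id, 3, pos, 1.0, prev))
            prev = next_id
            next_id += 1
        open_ends.append(prev)
    tree = NeuronTree(nodes)
    tree.validate()
    return tree
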