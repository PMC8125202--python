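"""Shared fixtures and independent brute-force oracles.

The oracles here (flood fill, point-in-convex-polygon, rotating-grid minimum
rectangle) are deliberately naive re-implementations kept independent of the
package's code paths, so they can serve as ground truth in equivalence tests.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from tmjgap import PhantomSpec, generate_phantom, measure_tmj
from tmjgap.head_segmentation import segment_tmj_head
from tmjgap.preprocess import curvature_flow_denoise
from tmjgap.reference_geometry import (extract_reference_slice, longest_section,
                                       reference_plane)
from tmjgap.volume_io import crop_voi


# ---------------------------------------------------------------- oracles

def flood_fill_border_oracle(mask: np.ndarray) -> np.ndarray:
    """Remove border-touching 8-connected components by BFS from the border."""
    mask = mask.astype(bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    stack = [(r, c) for r in range(h) for c in (0, w - 1) if mask[r, c]]
    stack += [(r, c) for c in range(w) for r in (0, h - 1) if mask[r, c]]
    while stack:
        r, c = stack.pop()
        if not (0 <= r < h and 0 <= c < w) or seen[r, c] or not mask[r, c]:
            continue
        seen[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                stack.append((r + dr, c + dc))
    return mask & ~seen


def point_in_hull_oracle(component: np.ndarray) -> np.ndarray:
    """Filled convex hull of a component's pixel centers by a brute-force
    point-in-convex-polygon (half-plane sign) test."""
    rr, cc = np.nonzero(component)
    pts = np.column_stack([rr, cc]).astype(float)
    from scipy.spatial import ConvexHull
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    out = np.zeros_like(component, dtype=bool)
    gr, gc = np.meshgrid(np.arange(component.shape[0]),
                         np.arange(component.shape[1]), indexing="ij")
    q = np.column_stack([gr.ravel(), gc.ravel()]).astype(float)
    inside = np.ones(q.shape[0], dtype=bool)
    n = len(verts)
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        cross = (b[0] - a[0]) * (q[:, 1] - a[1]) - (b[1] - a[1]) * (q[:, 0] - a[0])
        inside &= cross <= 1e-9  # ConvexHull vertices are clockwise in (r, c)?
    # orientation-agnostic: accept either sign convention
    inside2 = np.ones(q.shape[0], dtype=bool)
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        cross = (b[0] - a[0]) * (q[:, 1] - a[1]) - (b[1] - a[1]) * (q[:, 0] - a[0])
        inside2 &= cross >= -1e-9
    keep = inside if inside.sum() >= inside2.sum() else inside2
    out[gr.ravel()[keep], gc.ravel()[keep]] = True
    return out


def rotating_grid_min_rect_area(points: np.ndarray, step_deg: float = 0.1) -> float:
    """Exhaustive rotation-grid minimum enclosing-rectangle area."""
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    c, s = np.cos(angles), np.sin(angles)
    p1 = points[:, 0][:, None] * c[None, :] + points[:, 1][:, None] * s[None, :]
    p2 = -points[:, 0][:, None] * s[None, :] + points[:, 1][:, None] * c[None, :]
    w = p1.max(axis=0) - p1.min(axis=0)
    h = p2.max(axis=0) - p2.min(axis=0)
    return float(np.min(w * h))


def random_convex_mask(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """Rasterised filled convex polygon from random points (always >= 3 px)."""
    from scipy.spatial import ConvexHull
    while True:
        pts = rng.uniform(6, size - 6, size=(rng.integers(4, 12), 2))
        try:
            hull = ConvexHull(pts)
        except Exception:
            continue
        verts = pts[hull.vertices]
        from skimage.draw import polygon
        rr, cc = polygon(verts[:, 0], verts[:, 1], shape=(size, size))
        if rr.size >= 3:
            mask = np.zeros((size, size), dtype=bool)
            mask[rr, cc] = True
            if np.unique(rr).size > 1 and np.unique(cc).size > 1:
                return mask


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def sphere_run():
    """One full pipeline run on the default concentric sphere phantom
    (R = 6 mm, gap 2 mm, 0.3 mm isotropic voxels), shared across tests."""
    spec = PhantomSpec(shape=(80, 80, 80), seed=1)
    vol, truth, voi = generate_phantom(spec)
    cropped = crop_voi(vol, voi)
    den = curvature_flow_denoise(cropped)
    stack = segment_tmj_head(den)
    sec = longest_section(stack)
    plane = reference_plane(sec)
    ref = extract_reference_slice(den, stack, plane, "left")
    m = measure_tmj(vol, voi, "left")
    return SimpleNamespace(spec=spec, vol=vol, truth=truth, voi=voi,
                           cropped=cropped, den=den, stack=stack, sec=sec,
                           plane=plane, ref=ref, measurement=m)
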