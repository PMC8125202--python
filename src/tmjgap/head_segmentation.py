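"""Per-axial-slice condyle (TMJ head) segmentation.

Each slice of the VOI is classified independently with a Gaussian mixture of
the voxel pseudo-HU values fitted by EM: near the joint the histogram is
dominated by a large air peak with the soft-tissue and bone populations to its
right, so a pixel is called bone when its maximum-posterior component is the
component with the highest mean.  Postprocessing then removes every component
touching the ROI border (other skull structures enter the VOI from its edges),
replaces the remaining components by their filled convex hulls (the condyle is
nearly convex, while its trabecular interior segments poorly) and finally
keeps the largest 3D-connected component across the stack as the TMJ head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.morphology import convex_hull_image
from sklearn.mixture import GaussianMixture

from .errors import SegmentationError
from .volume_io import MaskStack, Volume3D

# 2D connectivity 8 (skimage connectivity=2), 3D connectivity 26: favours
# keeping thin oblique bone connected.
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationConfig:
    components: int = 3
    seed: int = 0
    tol: float = 1e-4          # convergence tol on mean log-likelihood
    var_floor: float = 1.0     # pseudo-HU^2


@dataclass
class GMMFit:
    """A fitted 1D Gaussian mixture, components sorted by ascending mean."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        order = np.argsort(self.means)
        self.means = np.asarray(self.means, dtype=float)[order]
        self.variances = np.asarray(self.variances, dtype=float)[order]
        self.weights = np.asarray(self.weights, dtype=float)[order]
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise SegmentationError(f"invalid mixture weights {self.weights}")
        if np.any(self.variances <= 0):
            raise SegmentationError(f"non-positive variance in {self.variances}")

    @property
    def n_components(self) -> int:
        return self.means.size

    def log_responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Unnormalised per-component log posterior, shape (K,) + x.shape."""
        x = np.asarray(x, dtype=float)
        mu = self.means.reshape((-1,) + (1,) * x.ndim)
        var = self.variances.reshape((-1,) + (1,) * x.ndim)
        w = self.weights.reshape((-1,) + (1,) * x.ndim)
        return np.log(w) - 0.5 * np.log(2 * np.pi * var) - 0.5 * (x - mu) ** 2 / var

    def decision_boundary(self, lo: int, hi: int) -> float:
        """Intensity where the weighted densities of components ``lo`` < ``hi``
        cross (the maximum-posterior decision boundary between them),
        restricted to the interval between their means."""
        m1, v1, w1 = self.means[lo], self.variances[lo], self.weights[lo]
        m2, v2, w2 = self.means[hi], self.variances[hi], self.weights[hi]
        # log w1 - (x-m1)^2/2v1 - log sqrt(v1) = log w2 - (x-m2)^2/2v2 - log sqrt(v2)
        a = 0.5 * (1.0 / v1 - 1.0 / v2)
        b = m2 / v2 - m1 / v1
        c = 0.5 * (m1 ** 2 / v1 - m2 ** 2 / v2) \
            + np.log(w2 / w1) + 0.5 * np.log(v1 / v2)
        if abs(a) < 1e-300:
            if b == 0:
                return 0.5 * (m1 + m2)
            return float(-c / b)
        disc = b * b - 4 * a * c
        if disc < 0:
            return 0.5 * (m1 + m2)
        roots = np.array([(-b - np.sqrt(disc)) / (2 * a),
                          (-b + np.sqrt(disc)) / (2 * a)])
        inside = roots[(roots >= m1) & (roots <= m2)]
        if inside.size:
            return float(inside[0])
        return float(roots[np.argmin(np.abs(roots - 0.5 * (m1 + m2)))])


def fit_gmm_slice(slice_values: np.ndarray, K: int = 3, seed: int = 0,
                  tol: float = 1e-4, var_floor: float = 1.0) -> GMMFit:
    """Fit a K-component Gaussian mixture to one slice's voxel values by EM.

    Initialisation is deterministic: component means at evenly spread
    percentiles of the slice values (10/50/90 for K=3), equal weights and the
    sample variance, so the fit is reproducible for a fixed seed.
    """
    x = np.asarray(slice_values, dtype=float).ravel()
    if np.unique(x).size < K:
        raise SegmentationError(f"slice has fewer than K={K} distinct values")

    def run(init_kwargs):
        gm = GaussianMixture(
            n_components=K,
            covariance_type="spherical",
            tol=tol,
            reg_covar=var_floor,
            max_iter=500,
            n_init=1,
            random_state=seed,
            **init_kwargs,
        )
        gm.fit(x.reshape(-1, 1))
        return gm

    qs = np.linspace(10, 90, K) if K > 1 else np.array([50.0])
    means_init = np.percentile(x, qs)
    # per-component variance from the nearest-mean partition: a single global
    # variance would drown the component separation and stall EM in a merged
    # local optimum
    assign = np.argmin(np.abs(x[:, None] - means_init[None, :]), axis=1)
    vars_init = np.array([
        max(float(np.var(x[assign == j])) if np.any(assign == j) else var_floor,
            var_floor)
        for j in range(K)
    ])
    candidates = [run({
        "weights_init": np.full(K, 1.0 / K),
        "means_init": means_init.reshape(-1, 1),
        "precisions_init": 1.0 / vars_init,
    })]
    # second deterministic start (k-means): on slices where one tissue class
    # dominates, the percentile start can place two components inside that
    # class and EM stays in the merged local optimum
    if K > 1:
        candidates.append(run({"init_params": "kmeans"}))
    gm = max(candidates, key=lambda g: g.lower_bound_)

    means = gm.means_.ravel()
    variances = gm.covariances_.ravel()
    weights = gm.weights_
    if not np.all(np.isfinite(means)) or np.any(variances < var_floor * (1 - 1e-12)):
        raise SegmentationError("EM produced a degenerate fit despite variance floor")
    return GMMFit(means, variances, weights)


def classify_bone(slice_values: np.ndarray, fit: GMMFit) -> np.ndarray:
    """Bone mask: pixels whose maximum-posterior component has the highest mean."""
    x = np.asarray(slice_values, dtype=float)
    logr = fit.log_responsibilities(x)
    return np.argmax(logr, axis=0) == fit.n_components - 1


def remove_border_components(mask: np.ndarray) -> np.ndarray:
    """Delete every 8-connected foreground component touching the 2D ROI border."""
    mask = np.asarray(mask, dtype=bool)
    labels = sk_label(mask, connectivity=2)
    border = np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
    ])
    kill = np.unique(border[border > 0])
    if kill.size == 0:
        return mask.copy()
    return mask & ~np.isin(labels, kill)


def fill_convex_hulls(mask: np.ndarray) -> np.ndarray:
    """Replace each 8-connected component by the filled convex hull of its
    pixel centers.  Idempotent."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    out = np.zeros_like(mask)
    for obj_slice, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        comp = labels[obj_slice] == lab
        rr, cc = np.nonzero(comp)
        # degenerate (point/collinear) components are their own hulls
        pts = np.column_stack([rr, cc]).astype(float)
        if rr.size < 3 or np.linalg.matrix_rank(pts - pts[0]) < 2:
            out[obj_slice] |= comp
            continue
        hull = convex_hull_image(comp, offset_coordinates=False)
        out[obj_slice] |= hull | comp
    return out


def keep_largest_component(stack: MaskStack) -> MaskStack:
    """Keep only the largest 26-connected 3D component of the stack.

    On a tie the component whose minimal (slice, row, col) index comes first
    is kept (labelling is in raster-scan order, so this is deterministic).
    """
    if not stack.data.any():
        raise SegmentationError("no bone found in VOI")
    labels, n = ndi.label(stack.data, structure=_STRUCT_3D)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))  # first maximal label = smallest min index
    return MaskStack(labels == keep, stack.spacing)


def segment_tmj_head(vol: Volume3D, cfg: SegmentationConfig = SegmentationConfig()) -> MaskStack:
    """Full per-slice segmentation pipeline: GMM classify, border removal,
    hull fill, then the largest 3D component across the stack."""
    nz = vol.shape[0]
    data = np.zeros(vol.shape, dtype=bool)
    for k in range(nz):
        sl = vol.values[k]
        fit = fit_gmm_slice(sl, K=cfg.components, seed=cfg.seed,
                            tol=cfg.tol, var_floor=cfg.var_floor)
        m = classify_bone(sl, fit)
        m = remove_border_components(m)
        m = fill_convex_hulls(m)
        data[k] = m
    stack = keep_largest_component(MaskStack(data, vol.spacing))
    if stack.data[0].any():
        warnings.warn(
            "TMJ head present on the uppermost VOI slice; the uppermost-slice "
            "assumption (no condyle on slice 0) is violated", stacklevel=2)
    return stack
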