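"""Reference cross-section geometry.

The measurement plane pi_V is the vertical plane through the midpoint of the
condyle's longest axial-projection section, perpendicular to it.  Per slice, a
minimum-area rectangle around the segmented head is built, the contact points
of its shorter sides with the head are collected, and the globally most
spread-out pair of contact points defines the section P0-P1.  The volume is
then rotated about the vertical axis so pi_V coincides with a grid plane, and
the resampled 2D slice (with a freshly classified bone mask, no hole filling,
no largest-component restriction so the fossa survives) is the base for all
gap measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from shapely.geometry import MultiPoint, Polygon

from .errors import GeometryError
from .head_segmentation import SegmentationConfig, classify_bone, fit_gmm_slice
from .volume_io import MaskStack, Volume3D

AIR_FILL = -1000.0  # pseudo-HU value for out-of-volume samples


@dataclass(frozen=True)
class GeometryConfig:
    contact_tol_voxels: float = 0.75  # fraction of the in-plane voxel diagonal


@dataclass
class MinAreaRect:
    """Minimum-area enclosing rectangle of a component's pixel centers (mm)."""

    corners: np.ndarray              # (4, 2), consecutive corners
    shorter_sides: Tuple[np.ndarray, np.ndarray]  # each (2, 2): endpoints
    is_square: bool

    @property
    def side_lengths(self) -> Tuple[float, float]:
        e0 = np.linalg.norm(self.corners[1] - self.corners[0])
        e1 = np.linalg.norm(self.corners[2] - self.corners[1])
        return (min(e0, e1), max(e0, e1))

    @property
    def area(self) -> float:
        a, b = self.side_lengths
        return a * b


@dataclass
class LongestSection:
    p0: np.ndarray          # (2,) axial-plane mm
    p1: np.ndarray
    slice0: int
    slice1: int

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))


@dataclass
class ReferencePlane:
    """Vertical plane through ``anchor``, normal at ``azimuth_deg`` in the
    axial plane (azimuth of the P0->P1 section, normalised to [-90, 90))."""

    anchor: np.ndarray      # (2,) mm
    azimuth_deg: float

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.azimuth_deg = normalize_azimuth(self.azimuth_deg)

    @property
    def normal(self) -> np.ndarray:
        b = math.radians(self.azimuth_deg)
        return np.array([math.cos(b), math.sin(b)])

    @property
    def in_plane_direction(self) -> np.ndarray:
        """Unit direction of the plane's trace in the axial plane (+u axis)."""
        b = math.radians(self.azimuth_deg)
        return np.array([-math.sin(b), math.cos(b)])


@dataclass
class ReferenceSlice:
    """The 2D resampled image in pi_V plus its bone mask.

    In-plane coordinates: ``u`` horizontal (col * du), ``v`` vertical
    (row * dv, dv = dz, increasing inferiorly / downward in the image).  The
    mapping uv -> volume mm is an isometry.  ``frontal_sign`` tells which u
    direction the frontal (anterior) side labels map to (+1 or -1), resolved
    from the user-supplied joint laterality.
    """

    image: np.ndarray       # (nz, ny) pseudo-HU
    mask: np.ndarray        # (nz, ny) bool, GMM bone, unfilled
    du: float
    dv: float
    anchor: np.ndarray      # (2,) axial mm, on the plane
    anchor_u: float         # u coordinate of the anchor
    azimuth_deg: float
    laterality: str
    frontal_sign: int
    bone_threshold: Optional[float] = None  # soft/bone decision boundary, pseudo-HU
    soft_level: Optional[float] = None      # soft-tissue class mean, pseudo-HU

    @property
    def extent_uv(self) -> Tuple[float, float]:
        nz, ny = self.image.shape
        return ((ny - 1) * self.du, (nz - 1) * self.dv)

    def uv_to_xyz(self, u: float, v: float) -> np.ndarray:
        b = math.radians(self.azimuth_deg)
        e = np.array([-math.sin(b), math.cos(b)])
        xy = self.anchor + (u - self.anchor_u) * e
        return np.array([xy[0], xy[1], v])


def normalize_azimuth(angle_deg: float) -> float:
    """Map an axial-plane direction angle to [-90, 90) (mod 180, centred on 0
    so that near-zero section directions keep a stable u-axis orientation)."""
    return float((angle_deg + 90.0) % 180.0 - 90.0)


def min_area_rectangle(points: np.ndarray) -> MinAreaRect:
    """Minimum-area enclosing rectangle of 2D points (mm), via rotating
    calipers over the convex hull edges.

    Raises GeometryError for degenerate (collinear / too few) point sets.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 3:
        raise GeometryError("need >= 3 points for a minimum-area rectangle")
    geom = MultiPoint([tuple(p) for p in points]).minimum_rotated_rectangle
    if not isinstance(geom, Polygon):
        raise GeometryError("degenerate (collinear) component")
    corners = np.asarray(geom.exterior.coords)[:4]
    e0 = float(np.linalg.norm(corners[1] - corners[0]))
    e1 = float(np.linalg.norm(corners[2] - corners[1]))
    is_square = abs(e0 - e1) < 1e-9
    if e0 <= e1:
        shorter = (np.array([corners[0], corners[1]]), np.array([corners[2], corners[3]]))
    else:
        shorter = (np.array([corners[1], corners[2]]), np.array([corners[3], corners[0]]))
    return MinAreaRect(corners=corners, shorter_sides=shorter, is_square=is_square)


def side_contact_point(points: np.ndarray, side: np.ndarray, tol: float) -> np.ndarray:
    """Mean of the component's pixel centers within ``tol`` of the side's
    line, projected onto the side.

    ``side`` is a (2, 2) segment (one shorter side of the component's
    min-area rectangle); ``tol`` guards rasterisation (for an exact rectangle
    the extreme points lie on the side).
    """
    points = np.asarray(points, dtype=float)
    a, b = np.asarray(side, dtype=float)
    d = b - a
    length = np.linalg.norm(d)
    if length == 0:
        raise GeometryError("zero-length rectangle side")
    d = d / length
    n = np.array([-d[1], d[0]])
    rel = points - a
    dist = np.abs(rel @ n)
    t = rel @ d
    sel = (dist <= tol) & (t >= -tol) & (t <= length + tol)
    if not np.any(sel):
        raise GeometryError("no component pixel in contact with the rectangle side")
    t_mean = float(np.mean(t[sel]))
    return a + t_mean * d


def _pixel_centers_mm(mask2d: np.ndarray, dx: float, dy: float) -> np.ndarray:
    rr, cc = np.nonzero(mask2d)
    return np.column_stack([cc * dx, rr * dy])


def _diameter_endpoints(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Endpoints of the point set's diameter (fallback for degenerate slices)."""
    if points.shape[0] > 3:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except Exception:
            pass  # collinear: brute force over all points
    best, pair = -1.0, (points[0], points[0])
    for i in range(points.shape[0]):
        d = np.linalg.norm(points - points[i], axis=1)
        j = int(np.argmax(d))
        if d[j] > best:
            best, pair = float(d[j]), (points[i], points[j])
    return pair


def _slice_contacts(points: np.ndarray, tol: float) -> Tuple[np.ndarray, np.ndarray]:
    """Contact points of the two shorter min-rect sides with the component.

    For a square rectangle (shorter-side tie) the side pair whose contact
    points are farther apart is used: it maximises the candidate section,
    consistent with the longest-section objective.
    """
    rect = min_area_rectangle(points)
    p0 = side_contact_point(points, rect.shorter_sides[0], tol)
    p1 = side_contact_point(points, rect.shorter_sides[1], tol)
    if rect.is_square:
        c = rect.corners
        other = (np.array([c[1], c[2]]), np.array([c[3], c[0]]))
        # identify which pair `shorter_sides` used; compare with the other pair
        if np.allclose(rect.shorter_sides[0], np.array([c[0], c[1]])):
            alt = other
        else:
            alt = (np.array([c[0], c[1]]), np.array([c[2], c[3]]))
        try:
            q0 = side_contact_point(points, alt[0], tol)
            q1 = side_contact_point(points, alt[1], tol)
            if np.linalg.norm(q1 - q0) > np.linalg.norm(p1 - p0):
                return q0, q1
        except GeometryError:
            pass
    return p0, p1


def longest_section(stack: MaskStack, cfg: GeometryConfig = GeometryConfig()) -> LongestSection:
    """Longest 2D-projected section between per-slice shorter-side contact
    points, searched globally over all collected endpoint candidates."""
    dx, dy = stack.spacing[0], stack.spacing[1]
    tol = cfg.contact_tol_voxels * math.hypot(dx, dy)
    p0_lst, p1_lst = [], []
    for k in stack.nonempty_slices:
        points = _pixel_centers_mm(stack.data[k], dx, dy)
        try:
            p0, p1 = _slice_contacts(points, tol)
        except GeometryError:
            if points.shape[0] < 2:
                continue
            p0, p1 = _diameter_endpoints(points)
        p0_lst.append((p0, int(k)))
        p1_lst.append((p1, int(k)))
    if not p0_lst:
        raise GeometryError("all slices degenerate: no section candidates")
    best = None
    for (p0, k0), (p1, k1) in product(p0_lst, p1_lst):
        d = float(np.linalg.norm(p1 - p0))
        if best is None or d > best[0]:
            best = (d, p0, p1, k0, k1)
    d, p0, p1, k0, k1 = best
    if d <= 0:
        raise GeometryError("degenerate zero-length longest section")
    return LongestSection(p0=np.asarray(p0), p1=np.asarray(p1), slice0=k0, slice1=k1)


def reference_plane(sec: LongestSection) -> ReferencePlane:
    """Perpendicular-bisector plane of the longest section: vertical, through
    the section midpoint, normal along P0->P1."""
    d = sec.p1 - sec.p0
    if np.linalg.norm(d) == 0:
        raise GeometryError("zero-length section")
    azimuth = math.degrees(math.atan2(d[1], d[0]))
    return ReferencePlane(anchor=(sec.p0 + sec.p1) / 2.0, azimuth_deg=azimuth)


def rotate_axial(vol: Volume3D, center_xy, angle_deg: float,
                 fill: float = AIR_FILL) -> Volume3D:
    """Rotate the volume about the vertical axis through ``center_xy`` (mm).

    Output point q samples input point c + R(angle) (q - c), with bilinear
    interpolation per axial slice and ``fill`` outside the volume.
    """
    return _resample_axial(vol, angle_deg, pivot_out=center_xy,
                           pivot_in=center_xy, fill=fill)


def _resample_axial(vol: Volume3D, angle_deg: float, pivot_out, pivot_in,
                    fill: float) -> Volume3D:
    dx, dy, _ = vol.spacing
    nz, ny, nx = vol.shape
    b = math.radians(angle_deg)
    cb, sb = math.cos(b), math.sin(b)
    X, Y = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dy)
    qx = X - pivot_out[0]
    qy = Y - pivot_out[1]
    px = pivot_in[0] + cb * qx - sb * qy
    py = pivot_in[1] + sb * qx + cb * qy
    coords = np.stack([py / dy, px / dx])
    out = np.empty_like(vol.values)
    for k in range(nz):
        out[k] = ndi.map_coordinates(vol.values[k], coords, order=1,
                                     mode="constant", cval=fill)
    return Volume3D(out, vol.spacing, vol.origin)


def extract_reference_slice(vol: Volume3D, stack: MaskStack, plane: ReferencePlane,
                            laterality: str = "left",
                            seg_cfg: SegmentationConfig = SegmentationConfig()) -> ReferenceSlice:
    """Resample the vertical reference slice and re-segment its bone.

    The whole volume is rotated about the vertical axis through the plane
    anchor so that pi_V becomes a grid plane (trilinear in-plane sampling,
    out-of-volume fill -1000); bone on the extracted slice is re-classified
    with the per-slice GMM, without hole filling and without the
    largest-component restriction, so the acetabulum survives.
    """
    if laterality not in ("left", "right"):
        raise ValueError(f"laterality must be 'left' or 'right', got {laterality!r}")
    dx, dy, _ = vol.spacing
    nz, ny, nx = vol.shape
    ax, ay = plane.anchor
    if not (0 <= ax <= (nx - 1) * dx and 0 <= ay <= (ny - 1) * dy):
        raise GeometryError(f"plane anchor {plane.anchor} outside the volume")
    j = int(round(ax / dx))
    anchor_g = (j * dx, ay)
    rotated = _resample_axial(vol, plane.azimuth_deg, pivot_out=anchor_g,
                              pivot_in=(ax, ay), fill=AIR_FILL)
    image = rotated.values[:, :, j].copy()  # (nz, ny): rows v=z, cols u=y

    # fit on in-volume samples only: the constant out-of-volume fill would
    # otherwise add a spurious low peak that eats a mixture component
    in_vol = image > AIR_FILL + 0.5
    fit_values = image[in_vol] if in_vol.any() else image
    fit = fit_gmm_slice(fit_values, K=seg_cfg.components, seed=seg_cfg.seed,
                        tol=seg_cfg.tol, var_floor=seg_cfg.var_floor)
    mask = classify_bone(image, fit)

    # Convention: anterior (frontal) lies at smaller u for a right joint and
    # at larger u for a left joint.
    frontal_sign = 1 if laterality == "left" else -1
    # soft/bone decision boundary: used to validate that a profile edge is a
    # genuine soft-tissue -> bone crossing rather than an interpolation graze
    bone_thr = fit.decision_boundary(fit.n_components - 2, fit.n_components - 1) \
        if fit.n_components >= 2 else float(fit.means[-1])
    return ReferenceSlice(
        image=image, mask=mask, du=dy, dv=vol.dz,
        anchor=np.asarray(plane.anchor, dtype=float), anchor_u=float(ay),
        azimuth_deg=plane.azimuth_deg, laterality=laterality,
        frontal_sign=frontal_sign, bone_threshold=bone_thr,
        soft_level=float(fit.means[-2]) if fit.n_components >= 2 else None,
    )
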