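"""Synthetic CBCT-like phantoms of a condyle/fossa pair with known truths.

The condyle is a sphere or ellipsoid of bone-like intensity; the fossa is the
whole region above the condyle equator lying outside the gap-inflated condyle
surface, so its inner surface sits a controllable gap above and around the
head.  Because that region reaches the VOI borders on every axial slice it is
deleted by border-component removal during head segmentation -- exactly how
the real temporal bone, connected to the rest of the skull, is discarded --
while it survives on the reference slice, where no border removal is applied.
An air band along the +y edge of the grid keeps all three intensity classes
(air, soft tissue, bone) present on every slice, and the joint gap itself is
soft tissue.  The intensity regime is deliberately low-contrast (bone barely
above 200 pseudo-HU) so the mixture-model segmentation is actually exercised.

All ground truths (gap widths, plane azimuth, tangent angles) derive from the
analytic membership functions, by closed form where available and by
fine-step ray casting otherwise; they depend only on the geometry, never on
the noise seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import VolumeError
from .reference_geometry import ReferenceSlice, normalize_azimuth
from .volume_io import VOIBox, Volume3D


@dataclass
class PhantomSpec:
    shape: Tuple[int, int, int] = (128, 128, 128)       # (nz, ny, nx)
    spacing: Tuple[float, float, float] = (0.3, 0.3, 0.3)
    radius: float = 6.0                 # sphere radius; ignored if half_axes set
    half_axes: Optional[Tuple[float, float, float]] = None  # (a, b, c), a >= b
    azimuth_deg: float = 0.0            # long-axis azimuth in the axial plane
    gap: float = 2.0                    # uniform fossa inner-surface offset, mm
    fossa_offset: Tuple[float, float] = (0.0, 0.0)      # in-plane fossa shift, mm
    condyle_center: Optional[Tuple[float, float, float]] = None
    air_band_mm: float = 5.0            # air slab along the +y grid edge
    bone_mean: float = 180.0
    soft_mean: float = -60.0
    air_mean: float = -950.0
    noise_sigma: float = 25.0
    seed: int = 0
    cavity_radius: float = 0.0          # internal soft cavity (tests hull fill)
    neck_radius_frac: float = 0.55      # condylar neck radius as fraction of b
    distractor: bool = False            # border-touching bone block
    voi_headroom_mm: float = 0.9        # VOI top above the fossa roof
    voi_below_mm: float = 2.0

    @property
    def abc(self) -> Tuple[float, float, float]:
        if self.half_axes is not None:
            a, b, c = self.half_axes
            if a < b:
                raise VolumeError("half_axes must satisfy a >= b")
            return float(a), float(b), float(c)
        r = float(self.radius)
        return r, r, r

    @property
    def center(self) -> np.ndarray:
        if self.condyle_center is not None:
            return np.asarray(self.condyle_center, dtype=float)
        nz, ny, nx = self.shape
        dx, dy, dz = self.spacing
        cx = (nx - 1) * dx / 2.0
        cy = ((ny - 1) * dy - self.air_band_mm) / 2.0
        cz = 0.55 * (nz - 1) * dz
        return np.array([cx, cy, cz])

    def validate(self) -> None:
        a, b, c = self.abc
        if self.gap <= 0:
            raise VolumeError("gap must be > 0")
        if not (self.bone_mean > self.soft_mean > self.air_mean):
            raise VolumeError("need bone_mean > soft_mean > air_mean")
        nz, ny, nx = self.shape
        dx, dy, dz = self.spacing
        cx, cy, cz = self.center
        if not (cx - a >= 3 * dx and cx + a <= (nx - 4) * dx
                and cy - a >= 3 * dy and cy + a <= (ny - 4) * dy
                and cz - c >= 3 * dz and cz + c <= (nz - 4) * dz):
            raise VolumeError("condyle does not fit inside the grid with a "
                              ">= 3-voxel margin")
        if cy + a + self.gap > (ny - 1) * dy - self.air_band_mm:
            raise VolumeError("condyle/gap intrudes into the air band")


@dataclass
class PhantomTruth:
    """Analytic ground truths (invariant to the noise seed)."""

    r_c: float
    plane_azimuth_deg: float
    section_length: float
    p_top: np.ndarray            # (x, y, z) mm, top of the condyle
    p_a: np.ndarray              # highest fossa point above the head
    r_u_plus: Optional[float]    # gap width on the +u side of the reference slice
    r_u_minus: Optional[float]
    theta_t_deg: Optional[float]  # analytic tangent angle (circular section only)


def _rotated_inplane(X, Y, cx, cy, azimuth_deg):
    b = math.radians(azimuth_deg)
    dxv, dyv = X - cx, Y - cy
    xr = math.cos(b) * dxv + math.sin(b) * dyv
    yr = -math.sin(b) * dxv + math.cos(b) * dyv
    return xr, yr


def _condyle_contains(spec: PhantomSpec, X, Y, Z):
    a, b, c = spec.abc
    cx, cy, cz = spec.center
    xr, yr = _rotated_inplane(X, Y, cx, cy, spec.azimuth_deg)
    return (xr / a) ** 2 + (yr / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0


def _fossa_contains(spec: PhantomSpec, X, Y, Z):
    a, b, c = spec.abc
    g = spec.gap
    ox, oy = spec.fossa_offset
    cx, cy, cz = spec.center
    xr, yr = _rotated_inplane(X, Y, cx + ox, cy + oy, spec.azimuth_deg)
    outside_inflated = (xr / (a + g)) ** 2 + (yr / (b + g)) ** 2 \
        + ((Z - cz) / (c + g)) ** 2 >= 1.0
    return (Z < cz) & outside_inflated


def _march(contains, origin: np.ndarray, direction: np.ndarray,
           step: float = 0.005, max_len: float = 50.0) -> float:
    """Distance from origin to the first point (exclusive of t=0) inside the
    region, by fine-step ray casting on the analytic membership function."""
    n = int(max_len / step)
    t = step * np.arange(1, n + 1)
    pts = origin[None, :] + t[:, None] * direction[None, :]
    hit = contains(pts[:, 0], pts[:, 1], pts[:, 2])
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        raise VolumeError("ray cast found no fossa within max_len")
    return float(t[idx[0]])


def _compute_truth(spec: PhantomSpec) -> PhantomTruth:
    a, b, c = spec.abc
    cx, cy, cz = spec.center
    fossa = lambda x, y, z: _fossa_contains(spec, x, y, z)

    p_top = np.array([cx, cy, cz - c])
    r_c = _march(fossa, p_top, np.array([0.0, 0.0, -1.0]))
    p_a = p_top + np.array([0.0, 0.0, -r_c])

    r_plus = r_minus = theta_t = None
    if abs(b - c) < 1e-12:
        # circular cross-section in the reference plane: analytic tangent
        R2 = b
        L = c + r_c  # |p_a - center|, p_a on the vertical through the center
        theta_t = math.degrees(math.asin(R2 / L))
        gamma = math.radians(90.0 - theta_t)
        bb = math.radians(spec.azimuth_deg)
        e = np.array([-math.sin(bb), math.cos(bb), 0.0])  # +u of the ref slice
        center = np.array([cx, cy, cz])
        sides = {}
        for s in (+1, -1):
            contact = center + s * R2 * math.sin(gamma) * e \
                + np.array([0.0, 0.0, -R2 * math.cos(gamma)])
            n = (contact - center) / R2
            sides[s] = _march(fossa, contact, n)
        r_plus, r_minus = sides[+1], sides[-1]

    return PhantomTruth(
        r_c=r_c,
        plane_azimuth_deg=normalize_azimuth(spec.azimuth_deg),
        section_length=2.0 * a,
        p_top=p_top, p_a=p_a,
        r_u_plus=r_plus, r_u_minus=r_minus,
        theta_t_deg=theta_t,
    )


def generate_phantom(spec: PhantomSpec) -> Tuple[Volume3D, PhantomTruth, VOIBox]:
    """Build the phantom volume, its analytic truth and a VOI whose uppermost
    slice clears the fossa roof (honouring the uppermost-slice assumption)."""
    spec.validate()
    nz, ny, nx = spec.shape
    dx, dy, dz = spec.spacing
    cx, cy, cz = spec.center
    a, b, c = spec.abc

    Z, Y, X = np.meshgrid(np.arange(nz) * dz, np.arange(ny) * dy,
                          np.arange(nx) * dx, indexing="ij")

    values = np.full(spec.shape, spec.soft_mean)
    values[_fossa_contains(spec, X, Y, Z)] = spec.bone_mean
    values[Y > (ny - 1) * dy - spec.air_band_mm] = spec.air_mean
    if spec.distractor:
        block = (X <= 2.0) & (np.abs(Y - cy) <= 3.0) & (np.abs(Z - cz) <= 3.0)
        values[block] = spec.bone_mean
    if spec.neck_radius_frac > 0:
        # mandibular neck: vertical cylinder from the head equator downward,
        # keeps bone present on every slice below the head
        r_neck = spec.neck_radius_frac * b
        neck = (Z >= cz) & ((X - cx) ** 2 + (Y - cy) ** 2 <= r_neck ** 2)
        values[neck] = spec.bone_mean
    values[_condyle_contains(spec, X, Y, Z)] = spec.bone_mean
    if spec.cavity_radius > 0:
        cav = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 \
            <= spec.cavity_radius ** 2
        values[cav] = spec.soft_mean

    rng = np.random.default_rng(spec.seed)
    values = values + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    roof_z = cz - (c + spec.gap)
    k_top = max(0, int(math.floor((roof_z - spec.voi_headroom_mm) / dz)))
    k_bot = min(nz, int(math.ceil((cz + c + spec.voi_below_mm) / dz)) + 1)
    voi = VOIBox(x_range=(0, nx), y_range=(0, ny), z_range=(k_top, k_bot))

    vol = Volume3D(values, spec.spacing)
    return vol, _compute_truth(spec), voi


def write_phantom_dicom(vol: Volume3D, directory) -> Path:
    """Write the volume as a valid single-frame CT DICOM series (signed
    16-bit, slope 1 / intercept 0), re-readable by volume_io.

    Slice k is placed at patient z = -k*dz so that superior -> inferior
    ordering matches descending DICOM z.  UIDs are derived deterministically
    from the series content layout.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nz, ny, nx = vol.shape
    dx, dy, dz = vol.spacing
    root = [f"tmjgap-phantom-{nz}x{ny}x{nx}-{dx}-{dy}-{dz}"]
    series_uid = generate_uid(entropy_srcs=root + ["series"])
    study_uid = generate_uid(entropy_srcs=root + ["study"])

    stored = np.clip(np.rint(vol.values), -32768, 32767).astype(np.int16)
    for k in range(nz):
        sop_uid = generate_uid(entropy_srcs=root + [f"slice{k}"])
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, -k * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]  # (between rows, between columns)
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = ny, nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = stored[k].tobytes()
        pydicom.dcmwrite(str(directory / f"slice_{k:04d}.dcm"), ds,
                         enforce_file_format=True)
    return directory


def circle_reference_slice(R: float = 6.0, d: float = 2.0,
                           spacing: float = 0.05, margin: float = 4.0,
                           bone_mean: float = 180.0, soft_mean: float = -60.0,
                           noise_sigma: float = 0.0, seed: int = 0,
                           fossa_offset_u: float = 0.0,
                           fossa_u_max: float = math.inf,
                           frontal_sign: int = 1) -> Tuple[ReferenceSlice, Dict]:
    """A synthetic reference slice with a circular head of radius ``R`` and a
    concentric (or u-shifted) fossa whose inner surface passes ``d`` above the
    head top, sampled at ``spacing`` mm.

    Exposes exact landmark truths for the tangent machinery: ``p_a`` sits on a
    grid point, so the analytic tangent angle arcsin(R / (R + d)) is checked
    free of landmark discretisation.  ``fossa_u_max`` clips the fossa on the
    +u side (bone absent beyond it) to exercise missing-shell errors.
    """
    half_w = R + d + margin
    uc = round(half_w / spacing) * spacing
    vc = round((R + d + margin) / spacing) * spacing
    n_u = int(round(2 * half_w / spacing)) + 1
    n_v = int(round((vc + R + margin) / spacing)) + 1
    U, V = np.meshgrid(np.arange(n_u) * spacing, np.arange(n_v) * spacing)

    dist2 = (U - uc) ** 2 + (V - vc) ** 2
    head = dist2 <= R ** 2
    fdist2 = (U - uc - fossa_offset_u) ** 2 + (V - vc) ** 2
    fossa = (V < vc) & (fdist2 >= (R + d) ** 2) & ((U - uc) <= fossa_u_max)
    mask = head | fossa

    image = np.where(mask, bone_mean, soft_mean).astype(float)
    if noise_sigma > 0:
        image += np.random.default_rng(seed).normal(0, noise_sigma, image.shape)

    ref = ReferenceSlice(image=image, mask=mask, du=spacing, dv=spacing,
                         anchor=np.array([0.0, 0.0]), anchor_u=0.0,
                         azimuth_deg=0.0,
                         laterality="left" if frontal_sign == 1 else "right",
                         frontal_sign=frontal_sign,
                         bone_threshold=0.5 * (bone_mean + soft_mean),
                         soft_level=soft_mean)

    p_top = np.array([uc, vc - R])
    fossa3 = lambda x, y, z: (z < vc) & ((x - uc - fossa_offset_u) ** 2
                                         + (z - vc) ** 2 >= (R + d) ** 2) \
        & ((x - uc) <= fossa_u_max)
    r_c = _march(fossa3, np.array([uc, 0.0, vc - R]), np.array([0.0, 0.0, -1.0]))
    p_a = np.array([uc, vc - R - r_c])
    L = R + r_c
    theta_t = math.degrees(math.asin(R / L))
    gamma = math.radians(90.0 - theta_t)
    sides = {}
    for s in (+1, -1):
        contact = np.array([uc + s * R * math.sin(gamma), vc - R * math.cos(gamma)])
        n = (contact - np.array([uc, vc])) / R
        try:
            sides[s] = _march(fossa3, np.array([contact[0], 0.0, contact[1]]),
                              np.array([n[0], 0.0, n[1]]))
        except VolumeError:
            sides[s] = None
    truth = {"p_a": p_a, "p_top": p_top, "theta_t_deg": theta_t, "r_c": r_c,
             "r_u_plus": sides[+1], "r_u_minus": sides[-1],
             "center": np.array([uc, vc]), "R": R}
    return ref, truth
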