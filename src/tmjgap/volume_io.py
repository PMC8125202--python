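"""Volumetric containers and I/O: DICOM series in, NIfTI masks and JSON reports out.

Index convention: ``values[k, r, c]`` where ``k`` is the axial slice index
numbered superior -> inferior, ``r`` the row (y) and ``c`` the column (x).
Physical mm coordinates are ``origin + index * spacing``; consequently the
local ``z`` coordinate *increases inferiorly*, i.e. "up" (superior) means
decreasing z.  Voxel indices are 0-based, index intervals half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Tuple

import nibabel as nib
import numpy as np
import pydicom

from .errors import VolumeError

log = logging.getLogger(__name__)


@dataclass
class Volume3D:
    """A 3D scalar image in pseudo-HU with anisotropic voxel spacing.

    CBCT grey values rescaled to a Hounsfield-like scale are not quantitatively
    reliable across devices; the pipeline only relies on contrast between air,
    soft tissue and bone, never on absolute calibration.
    """

    values: np.ndarray  # (nz, ny, nx), float
    spacing: Tuple[float, float, float]  # (dx, dy, dz) mm / voxel
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise VolumeError(f"expected a 3D grid, got ndim={self.values.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be strictly positive, got {self.spacing}")
        if any(n < 2 for n in self.values.shape):
            raise VolumeError(f"grid dimensions must be >= 2, got {self.values.shape}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def dx(self) -> float:
        return self.spacing[0]

    @property
    def dy(self) -> float:
        return self.spacing[1]

    @property
    def dz(self) -> float:
        return self.spacing[2]


@dataclass(frozen=True)
class VOIBox:
    """Manually chosen cuboid volume of interest, as half-open index ranges."""

    x_range: Tuple[int, int]
    y_range: Tuple[int, int]
    z_range: Tuple[int, int]

    def __post_init__(self):
        for name, (lo, hi) in (("x", self.x_range), ("y", self.y_range), ("z", self.z_range)):
            if hi <= lo:
                raise VolumeError(f"VOI {name}_range {lo, hi} is empty")
        if self.z_range[1] - self.z_range[0] < 3:
            raise VolumeError("VOI z_range must span at least 3 slices")

    def validate_within(self, vol: Volume3D) -> None:
        nz, ny, nx = vol.shape
        for name, (lo, hi), n in (
            ("x", self.x_range, nx),
            ("y", self.y_range, ny),
            ("z", self.z_range, nz),
        ):
            if lo < 0 or hi > n:
                raise VolumeError(
                    f"VOI {name}_range {lo, hi} outside volume bounds [0, {n})"
                )


@dataclass
class MaskStack:
    """Per-axial-slice binary condyle masks sharing the VOI grid."""

    data: np.ndarray  # (nz, ny, nx) bool
    spacing: Tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise VolumeError("mask stack must be 3D")

    def slice_mask(self, k: int) -> np.ndarray:
        return self.data[k]

    @property
    def nonempty_slices(self) -> np.ndarray:
        return np.flatnonzero(self.data.any(axis=(1, 2)))

    @property
    def first_head_slice(self) -> int:
        idx = self.nonempty_slices
        if idx.size == 0:
            raise VolumeError("mask stack is empty")
        return int(idx[0])

    @property
    def last_head_slice(self) -> int:
        idx = self.nonempty_slices
        if idx.size == 0:
            raise VolumeError("mask stack is empty")
        return int(idx[-1])


def read_dicom_series(directory) -> Volume3D:
    """Read a single-frame DICOM series into a physically calibrated volume.

    Slices are sorted by physical position into superior -> inferior order
    (descending DICOM patient z) and rescale slope/intercept are applied so
    the voxel values are pseudo-HU.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except pydicom.errors.InvalidDicomError:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if len(datasets) < 2:
        raise VolumeError(f"need >= 2 DICOM image files in {directory}, found {len(datasets)}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise VolumeError(f"mixed SeriesInstanceUIDs in {directory}: {sorted(map(str, uids))}")

    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) != 1:
        raise VolumeError(f"inconsistent PixelSpacing across slices: {sorted(spacings)}")
    row_spacing, col_spacing = spacings.pop()  # DICOM: (between rows, between cols)

    # superior -> inferior: descending patient z
    datasets.sort(key=lambda ds: -float(ds.ImagePositionPatient[2]))

    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    dz_steps = -np.diff(zs)
    if np.any(dz_steps <= 0):
        raise VolumeError("duplicate or non-monotone slice positions")
    dz = float(np.median(dz_steps))
    # the per-slice positions are decimal strings; prefer the exact
    # SliceThickness tag when it agrees with the measured inter-slice distance
    st = getattr(datasets[0], "SliceThickness", None)
    if st is not None and abs(float(st) - dz) < 1e-3:
        dz = float(st)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            log.warning("missing rescale tags in %s; assuming slope 1, intercept 0",
                        getattr(ds, "SOPInstanceUID", "?"))
            slope, intercept = 1.0, 0.0
        slices.append(arr * float(slope) + float(intercept))

    values = np.stack(slices, axis=0)
    first = datasets[0]
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        0.0,  # local z grows inferiorly from the most superior slice
    )
    return Volume3D(values, (float(col_spacing), float(row_spacing), dz), origin)


def crop_voi(vol: Volume3D, voi: VOIBox) -> Volume3D:
    """Restrict a volume to the VOI; spacing unchanged, origin shifted."""
    voi.validate_within(vol)
    (x0, x1), (y0, y1), (z0, z1) = voi.x_range, voi.y_range, voi.z_range
    values = vol.values[z0:z1, y0:y1, x0:x1].copy()
    ox, oy, oz = vol.origin
    dx, dy, dz = vol.spacing
    return Volume3D(values, vol.spacing, (ox + x0 * dx, oy + y0 * dy, oz + z0 * dz))


def write_mask_stack(masks: MaskStack, path) -> None:
    """Write a mask stack as one 3D binary NIfTI image (lossless round-trip)."""
    if masks.data.size == 0:
        raise VolumeError("refusing to write an empty mask stack")
    dx, dy, dz = masks.spacing
    # NIfTI stores (x, y, z); our array is (z, y, x)
    arr = np.transpose(masks.data.astype(np.uint8), (2, 1, 0))
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_mask_stack(path) -> MaskStack:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj).astype(bool)
    data = np.transpose(arr, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    return MaskStack(data, (float(zooms[0]), float(zooms[1]), float(zooms[2])))


def write_report(report: dict, path) -> None:
    """Write a measurement report as deterministic (sorted, fixed-format) JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
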