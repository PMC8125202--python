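"""Gap-width measurement on the reference slice.

Landmarks and widths (all in mm, reference-slice (u, v) coordinates):

* ``P_TMJh`` -- top of the condyle: midpoint of the reference plane's trace
  through the head mask on the uppermost head-bearing axial slice.
* ``P_TMJa`` -- highest point of the radiological fossa: first bone pixel
  straight above ``P_TMJh`` after the head's own bone run.
* ``r_C = |P_TMJa P_TMJh|`` -- the upper (vertical) gap width.
* The dorsal/frontal widths are found by sweeping a half-line from
  ``P_TMJa`` away from the vertical: the distance d(theta) to the first
  bone-entry edge on the intensity profile grows slowly while the line still
  crosses the head and jumps discontinuously once the line passes the tangent
  to the head.  The tangent angle theta^T is the mean of the fine bracketing
  angles; the perpendicular through the tangent contact point crosses the
  fossa at ``P_TMJaD`` / ``P_TMJaF``, giving ``r_D`` and ``r_F``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import MeasurementError, StageError
from .head_segmentation import SegmentationConfig, segment_tmj_head
from .preprocess import DenoiseConfig, curvature_flow_denoise
from .reference_geometry import (GeometryConfig, ReferencePlane, ReferenceSlice,
                                 extract_reference_slice, longest_section,
                                 reference_plane)
from .volume_io import MaskStack, VOIBox, Volume3D, crop_voi


@dataclass(frozen=True)
class SweepConfig:
    theta_max: float = 50.0        # degrees
    coarse_step: float = 5.0
    fine_step: float = 0.5
    step_threshold_mm: float = 1.0  # base jump threshold for d(theta)


@dataclass(frozen=True)
class ProfileConfig:
    step_factor: float = 0.5       # profile step = factor * min in-plane spacing
    peak_frac: float = 0.25        # derivative peak threshold, fraction of max |d'|
    min_offset_samples: int = 2    # skip the origin's own bone-exit peak


@dataclass
class Profile:
    """Intensity samples along a half-line in the reference slice."""

    positions: np.ndarray   # mm from origin, strictly increasing, uniform
    values: np.ndarray
    origin: np.ndarray      # (u, v) mm
    direction: np.ndarray   # unit (du, dv)

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass
class TangentResult:
    side: str                       # "dorsal" | "frontal"
    theta_below: float              # last angle still crossing the head (deg)
    theta_above: float
    theta_T: float                  # mean of the bracketing pair
    contact: np.ndarray             # tangent contact point (u, v) mm
    d_samples: Dict[float, Optional[float]]  # theta -> distance-to-first-slope
    u_sign: int                     # u direction of this side's half-lines


@dataclass
class TMJMeasurement:
    laterality: str
    plane_azimuth_deg: float
    section_length_mm: float
    p_tmjh: np.ndarray
    p_tmja: np.ndarray
    p_tmjd: np.ndarray
    p_tmjf: np.ndarray
    p_tmjad: np.ndarray
    p_tmjaf: np.ndarray
    r_c_mm: float
    r_d_mm: float
    r_f_mm: float
    theta_t_dorsal_deg: float
    theta_t_frontal_deg: float
    degenerate: Dict[str, bool]
    config_echo: Dict[str, object]

    def to_report(self) -> dict:
        return {
            "laterality": self.laterality,
            "plane_azimuth_deg": self.plane_azimuth_deg,
            "section_length_mm": self.section_length_mm,
            "r_C_mm": self.r_c_mm,
            "r_D_mm": self.r_d_mm,
            "r_F_mm": self.r_f_mm,
            "theta_T_dorsal_deg": self.theta_t_dorsal_deg,
            "theta_T_frontal_deg": self.theta_t_frontal_deg,
            "landmarks": {
                "P_TMJh": list(map(float, self.p_tmjh)),
                "P_TMJa": list(map(float, self.p_tmja)),
                "P_TMJD": list(map(float, self.p_tmjd)),
                "P_TMJF": list(map(float, self.p_tmjf)),
                "P_TMJaD": list(map(float, self.p_tmjad)),
                "P_TMJaF": list(map(float, self.p_tmjaf)),
            },
            "degenerate": dict(self.degenerate),
            "config_echo": dict(self.config_echo),
        }


def locate_head_top(stack: MaskStack, plane: ReferencePlane,
                    ref: ReferenceSlice) -> np.ndarray:
    """P_TMJh: midpoint of the plane-trace / head-mask intersection on the
    uppermost head-bearing axial slice, in reference-slice (u, v) mm."""
    i0 = stack.first_head_slice
    dx, dy = stack.spacing[0], stack.spacing[1]
    nz, ny = ref.image.shape
    e = plane.in_plane_direction
    us = np.arange(ny) * ref.du
    xy = ref.anchor[None, :] + (us - ref.anchor_u)[:, None] * e[None, :]
    cols = np.rint(xy[:, 0] / dx).astype(int)
    rows = np.rint(xy[:, 1] / dy).astype(int)
    inb = (cols >= 0) & (cols < stack.data.shape[2]) & \
          (rows >= 0) & (rows < stack.data.shape[1])
    occ = np.zeros(ny, dtype=bool)
    occ[inb] = stack.data[i0][rows[inb], cols[inb]]
    if not occ.any():
        raise MeasurementError(
            "reference plane trace misses the head mask on the top slice")
    # contiguous runs of occupancy
    padded = np.diff(np.concatenate([[0], occ.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    if starts.size > 1:
        warnings.warn("multiple plane/head intersection runs on the top slice; "
                      "using the longest", stacklevel=2)
    lengths = ends - starts
    i = int(np.argmax(lengths))  # tie -> first (deterministic)
    u_mid = 0.5 * (us[starts[i]] + us[ends[i]])
    # slice i0 holds head bone and slice i0-1 does not, so the head apex lies
    # between their sampling planes: estimate it at the interface, half a
    # slice above i0
    return np.array([u_mid, (i0 - 0.5) * ref.dv])


def locate_acetabulum_point(ref: ReferenceSlice, p_h: np.ndarray) -> np.ndarray:
    """P_TMJa: marching straight up from P_TMJh, skip the head's own bone run,
    return the first bone pixel after at least one non-bone sample."""
    nz, ny = ref.mask.shape
    col = int(round(p_h[0] / ref.du))
    if not 0 <= col < ny:
        raise MeasurementError("P_TMJh outside the reference slice")
    # start on the head's own bone if it is within a pixel of p_h (p_h may sit
    # on the inter-slice interface half a pixel above the first head row)
    row = min(nz - 1, int(math.floor(p_h[1] / ref.dv)) + 1)
    for cand in (row, int(round(p_h[1] / ref.dv)), row - 1):
        if 0 <= cand < nz and ref.mask[cand, col]:
            row = cand
            break
    if row < 0:
        raise MeasurementError("P_TMJh outside the reference slice")
    r = row
    while r >= 0 and ref.mask[r, col]:
        r -= 1
    if r < 0:
        raise MeasurementError(
            "acetabulum not in VOI: bone run reaches the top of the slice "
            "(no radiological gap above the head; VOI z_range too short or "
            "head/fossa contact)")
    while r >= 0 and not ref.mask[r, col]:
        r -= 1
    if r < 0:
        raise MeasurementError("acetabulum not in VOI (no bone above the gap)")
    # row r is the first (lowest) fossa bone pixel and row r+1 is gap; refine
    # the surface to sub-voxel by the soft/bone intensity crossing between
    # them, falling back to the half-pixel interface estimate
    v = (r + 0.5) * ref.dv
    thr = ref.bone_threshold
    if thr is not None and r + 1 < nz:
        hi, lo = float(ref.image[r, col]), float(ref.image[r + 1, col])
        if hi > thr > lo:
            v = (r + (thr - hi) / (lo - hi)) * ref.dv
    return np.array([col * ref.du, v])


def compute_rC(p_h: np.ndarray, p_a: np.ndarray) -> float:
    """Upper gap width: Euclidean distance, purely vertical by construction."""
    return float(np.linalg.norm(np.asarray(p_h, float) - np.asarray(p_a, float)))


def line_profile(ref: ReferenceSlice, origin, angle_signed_deg: float,
                 step: float, max_len: Optional[float] = None) -> Profile:
    """Bilinear intensity samples along the half-line from ``origin`` at the
    signed angle from the downward vertical (positive towards +u), truncated
    at the slice boundary."""
    u0, v0 = float(origin[0]), float(origin[1])
    b = math.radians(angle_signed_deg)
    d = np.array([math.sin(b), math.cos(b)])  # (du, dv), dv>0 is downward
    u_max, v_max = ref.extent_uv
    # analytic truncation at the in-bounds boundary
    tmax = np.inf
    for x0, dxc, hi in ((u0, d[0], u_max), (v0, d[1], v_max)):
        if dxc > 1e-12:
            tmax = min(tmax, (hi - x0) / dxc)
        elif dxc < -1e-12:
            tmax = min(tmax, (0.0 - x0) / dxc)
    if max_len is not None:
        tmax = min(tmax, max_len)
    if not np.isfinite(tmax) or tmax <= step:
        raise MeasurementError("profile leaves the slice immediately")
    t = np.arange(0.0, tmax, step)
    us = u0 + t * d[0]
    vs = v0 + t * d[1]
    vals = ndi.map_coordinates(ref.image, np.stack([vs / ref.dv, us / ref.du]),
                               order=1, mode="nearest")
    return Profile(positions=t, values=vals, origin=np.array([u0, v0]), direction=d)


def first_bone_entry(profile: Profile, peak_frac: float = 0.25,
                     min_offset_samples: int = 2,
                     min_value: Optional[float] = None) -> Optional[float]:
    """Position (mm) of the first positive local maximum of the profile's
    central-difference derivative exceeding ``peak_frac`` of the maximum
    absolute derivative, beyond ``min_offset_samples``; None if absent.

    Plateau peaks (exact ties on a clean step) report the plateau centre.
    If ``min_value`` is given, a candidate edge only counts as a soft -> bone
    crossing when the profile actually reaches that level within ~1 mm past
    the peak: a half-line merely grazing the head boundary produces a
    partial-volume bump whose derivative peaks but whose values never reach
    bone, and must not be mistaken for an entry into the head.
    """
    y = profile.values
    t = profile.positions
    if y.size < 3:
        return None
    dy = np.gradient(y, t)
    scale = float(np.max(np.abs(dy)))
    if scale <= 0:
        return None
    thr = peak_frac * scale
    n = dy.size
    window = max(2, int(math.ceil(1.0 / profile.step)))
    i = max(min_offset_samples + 1, 1)
    while i < n - 1:
        if dy[i] > thr and dy[i] >= dy[i - 1] and dy[i] >= dy[i + 1]:
            j = i
            while j + 1 < n - 1 and dy[j + 1] == dy[i]:
                j += 1
            if min_value is not None and \
                    float(np.median(y[i:min(n, j + 1 + window)])) < min_value:
                i = j + 1
                continue
            return float(0.5 * (t[i] + t[j]))
        i += 1
    return None


def _detect_step(ds: List[Optional[float]], base_threshold: float,
                 fixed_threshold: Optional[float] = None
                 ) -> Optional[Tuple[int, float]]:
    """First index i where d jumps from ds[i] to ds[i+1] by more than the
    threshold (or to None).  Sequential rule: threshold is
    max(base, 3 * median of increments seen so far) unless fixed."""
    prev_incs: List[float] = []
    for i in range(len(ds) - 1):
        if ds[i] is None:
            continue
        if fixed_threshold is not None:
            thr = fixed_threshold
        elif prev_incs:
            thr = max(base_threshold, 3.0 * float(np.median(prev_incs)))
        else:
            thr = base_threshold
        if ds[i + 1] is None:
            return i, thr
        inc = ds[i + 1] - ds[i]
        if inc > thr:
            return i, thr
        prev_incs.append(inc)
    return None


def tangent_from_distance_fn(d_fn: Callable[[float], Optional[float]],
                             cfg: SweepConfig = SweepConfig()
                             ) -> Tuple[float, float, float, Dict[float, Optional[float]]]:
    """Two-stage tangent search on a distance-to-first-slope function d(theta).

    Coarse sweep 0..theta_max at coarse_step; the first pair with a
    discontinuous jump (or a transition to None) brackets the tangent; the
    bracket is re-swept at fine_step and theta^T is the mean of the fine
    bracketing pair.  Returns (theta_below, theta_above, theta_T, samples).
    """
    coarse = np.arange(0.0, cfg.theta_max + 1e-9, cfg.coarse_step)
    samples: Dict[float, Optional[float]] = {}
    ds = []
    for th in coarse:
        d = d_fn(float(th))
        samples[float(th)] = d
        ds.append(d)
    if ds[0] is None:
        raise MeasurementError("d(0) undefined: no bone entry below P_TMJa")
    hit = _detect_step(ds, cfg.step_threshold_mm)
    if hit is None:
        raise MeasurementError(
            f"tangent not found: no d(theta) step up to {cfg.theta_max} deg "
            "(degenerate head shape)")
    i, thr = hit
    fine = np.arange(coarse[i], coarse[i + 1] + 1e-9, cfg.fine_step)
    fds = []
    for th in fine:
        d = d_fn(float(th))
        samples[float(th)] = d
        fds.append(d)
    fhit = _detect_step(fds, cfg.step_threshold_mm, fixed_threshold=thr)
    if fhit is None:
        # jump spread over several fine steps: take the largest increment
        incs = [(fds[j + 1] - fds[j]) if (fds[j] is not None and fds[j + 1] is not None)
                else math.inf if fds[j] is not None else -math.inf
                for j in range(len(fds) - 1)]
        j = int(np.argmax(incs))
    else:
        j = fhit[0]
    theta_below = float(fine[j])
    theta_above = float(fine[j + 1])
    return theta_below, theta_above, 0.5 * (theta_below + theta_above), samples


def tangent_sweep(ref: ReferenceSlice, p_a: np.ndarray, side: str,
                  sweep_cfg: SweepConfig = SweepConfig(),
                  prof_cfg: ProfileConfig = ProfileConfig()) -> TangentResult:
    """Sweep half-lines from P_TMJa on one side of the vertical and bracket
    the tangent to the head via the d(theta) discontinuity."""
    if side not in ("dorsal", "frontal"):
        raise ValueError(f"side must be 'dorsal' or 'frontal', got {side!r}")
    u_sign = ref.frontal_sign if side == "frontal" else -ref.frontal_sign
    step = prof_cfg.step_factor * min(ref.du, ref.dv)

    def d_fn(theta: float) -> Optional[float]:
        prof = line_profile(ref, p_a, u_sign * theta, step)
        if ref.soft_level is not None:
            # clip below the soft-tissue level: a later soft -> air drop (air
            # cells, out-of-volume fill) has larger contrast than the
            # soft -> bone edge of interest and would dominate the relative
            # derivative threshold
            prof = Profile(prof.positions,
                           np.maximum(prof.values, ref.soft_level),
                           prof.origin, prof.direction)
        return first_bone_entry(prof, prof_cfg.peak_frac,
                                prof_cfg.min_offset_samples,
                                min_value=ref.bone_threshold)

    th_below, th_above, th_T, samples = tangent_from_distance_fn(d_fn, sweep_cfg)
    d_contact = samples[th_below]
    if d_contact is None:  # cannot happen: theta_below still crosses the head
        raise MeasurementError("internal: no bone entry at theta_below")
    b = math.radians(u_sign * th_below)
    direction = np.array([math.sin(b), math.cos(b)])
    contact = np.asarray(p_a, float) + d_contact * direction
    return TangentResult(side=side, theta_below=th_below, theta_above=th_above,
                         theta_T=th_T, contact=contact, d_samples=samples,
                         u_sign=u_sign)


def _head_centroid_at(ref: ReferenceSlice, contact: np.ndarray) -> np.ndarray:
    """Centroid (u, v) of the bone component containing (or nearest to within
    2 px of) the tangent contact point."""
    labels, _ = ndi.label(ref.mask, structure=np.ones((3, 3), dtype=bool))
    nz, ny = ref.mask.shape
    r0 = int(round(contact[1] / ref.dv))
    c0 = int(round(contact[0] / ref.du))
    lab = 0
    best = np.inf
    for dr in range(-2, 3):
        for dc in range(-2, 3):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < nz and 0 <= c < ny and labels[r, c] > 0:
                d2 = dr * dr + dc * dc
                if d2 < best:
                    best, lab = d2, labels[r, c]
    if lab == 0:
        raise MeasurementError("tangent contact point is not on bone")
    rr, cc = np.nonzero(labels == lab)
    return np.array([cc.mean() * ref.du, rr.mean() * ref.dv])


def gap_width_at_tangent(ref: ReferenceSlice, tr: TangentResult
                         ) -> Tuple[float, np.ndarray]:
    """Gap width on the tangent perpendicular: march from the contact point
    towards the acetabulum on the bone mask; the distance to the first fossa
    bone pixel is r, the hit point is P_TMJaD / P_TMJaF."""
    b = math.radians(tr.u_sign * tr.theta_below)
    t = np.array([math.sin(b), math.cos(b)])
    normals = (np.array([t[1], -t[0]]), np.array([-t[1], t[0]]))
    centroid = _head_centroid_at(ref, tr.contact)
    outward = tr.contact - centroid
    n = normals[0] if normals[0] @ outward > normals[1] @ outward else normals[1]

    nz, ny = ref.mask.shape
    step = 0.5 * min(ref.du, ref.dv)
    u_max, v_max = ref.extent_uv
    s = 0.0
    in_head = True
    while True:
        p = tr.contact + s * n
        if not (0 <= p[0] <= u_max and 0 <= p[1] <= v_max):
            raise MeasurementError(
                f"fossa not found on the tangent perpendicular ({tr.side} side)")
        bone = ref.mask[int(round(p[1] / ref.dv)), int(round(p[0] / ref.du))]
        if in_head:
            if not bone:
                in_head = False
        elif bone:
            # the fossa surface lies between this and the previous sample
            return float(s - 0.5 * step), p
        s += step


def measure_tmj(vol: Volume3D, voi: VOIBox, laterality: str,
                denoise_cfg: DenoiseConfig = DenoiseConfig(),
                seg_cfg: SegmentationConfig = SegmentationConfig(),
                geom_cfg: GeometryConfig = GeometryConfig(),
                sweep_cfg: SweepConfig = SweepConfig(),
                prof_cfg: ProfileConfig = ProfileConfig()) -> TMJMeasurement:
    """Full measurement: crop -> denoise -> segment -> reference plane ->
    reference slice -> landmarks -> (r_C, r_D, r_F)."""

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:  # attach the stage name for the caller
            raise StageError(name, e) from e

    cropped = stage("crop_voi", crop_voi, vol, voi)
    den = stage("denoise", curvature_flow_denoise, cropped, denoise_cfg)
    stack = stage("segment", segment_tmj_head, den, seg_cfg)
    sec = stage("longest_section", longest_section, stack, geom_cfg)
    plane = stage("reference_plane", reference_plane, sec)
    ref = stage("reference_slice", extract_reference_slice, den, stack, plane,
                laterality, seg_cfg)
    p_h = stage("head_top", locate_head_top, stack, plane, ref)
    p_a = stage("acetabulum", locate_acetabulum_point, ref, p_h)
    r_c = compute_rC(p_h, p_a)

    tr_d = stage("tangent_dorsal", tangent_sweep, ref, p_a, "dorsal",
                 sweep_cfg, prof_cfg)
    tr_f = stage("tangent_frontal", tangent_sweep, ref, p_a, "frontal",
                 sweep_cfg, prof_cfg)
    r_d, p_ad = stage("gap_dorsal", gap_width_at_tangent, ref, tr_d)
    r_f, p_af = stage("gap_frontal", gap_width_at_tangent, ref, tr_f)

    voxel = min(ref.du, ref.dv)
    degenerate = {
        "r_C": r_c < voxel,
        "r_D": r_d < voxel,
        "r_F": r_f < voxel,
    }
    config_echo = {
        "denoise.time_step": denoise_cfg.time_step,
        "denoise.iterations": denoise_cfg.iterations,
        "segmentation.components": seg_cfg.components,
        "segmentation.seed": seg_cfg.seed,
        "segmentation.tol": seg_cfg.tol,
        "geometry.contact_tol_voxels": geom_cfg.contact_tol_voxels,
        "sweep.theta_max": sweep_cfg.theta_max,
        "sweep.coarse_step": sweep_cfg.coarse_step,
        "sweep.fine_step": sweep_cfg.fine_step,
        "sweep.step_threshold_mm": sweep_cfg.step_threshold_mm,
        "profile.step_factor": prof_cfg.step_factor,
        "voi": {"x_range": list(voi.x_range), "y_range": list(voi.y_range),
                "z_range": list(voi.z_range)},
    }
    return TMJMeasurement(
        laterality=laterality,
        plane_azimuth_deg=plane.azimuth_deg,
        section_length_mm=sec.length,
        p_tmjh=p_h, p_tmja=p_a,
        p_tmjd=tr_d.contact, p_tmjf=tr_f.contact,
        p_tmjad=p_ad, p_tmjaf=p_af,
        r_c_mm=r_c, r_d_mm=float(r_d), r_f_mm=float(r_f),
        theta_t_dorsal_deg=tr_d.theta_T, theta_t_frontal_deg=tr_f.theta_T,
        degenerate=degenerate, config_echo=config_echo,
    )
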