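import math

import numpy as np
import pytest

from tmjgap.errors import MeasurementError
from tmjgap.gap_measurement import (Profile, SweepConfig, compute_rC,
                                    first_bone_entry, gap_width_at_tangent,
                                    line_profile, locate_acetabulum_point,
                                    locate_head_top, measure_tmj,
                                    tangent_from_distance_fn, tangent_sweep)
from tmjgap.phantom import (PhantomSpec, circle_reference_slice,
                            generate_phantom)
from tmjgap.reference_geometry import ReferenceSlice
from tmjgap.volume_io import MaskStack


def _plain_ref(image, mask, spacing=0.5, frontal_sign=1, bone_threshold=60.0,
               anchor=(0.0, 0.0)):
    return ReferenceSlice(image=image.astype(float), mask=mask.astype(bool),
                          du=spacing, dv=spacing,
                          anchor=np.asarray(anchor, dtype=float),
                          anchor_u=float(anchor[1]),
                          azimuth_deg=0.0, laterality="left",
                          frontal_sign=frontal_sign,
                          bone_threshold=bone_threshold)


class TestLocateHeadTop:
    def test_sphere_phantom_apex(self, sphere_run):
        spec, voi = sphere_run.spec, sphere_run.voi
        p_h = locate_head_top(sphere_run.stack, sphere_run.plane, sphere_run.ref)
        apex_v = spec.center[2] - spec.radius - voi.z_range[0] * spec.spacing[2]
        assert p_h[1] == pytest.approx(apex_v, abs=spec.spacing[2])
        # u of the apex maps back to a point ~R-close to the condyle axis
        xyz = sphere_run.ref.uv_to_xyz(p_h[0], p_h[1])
        assert np.hypot(xyz[0] - spec.center[0],
                        xyz[1] - spec.center[1]) <= 2 * spec.spacing[0]

    def test_single_pixel_mask(self):
        data = np.zeros((3, 9, 9), bool)
        data[1, 4, 4] = True
        stack = MaskStack(data, (0.5, 0.5, 0.5))
        from tmjgap.reference_geometry import ReferencePlane
        plane = ReferencePlane(anchor=np.array([2.0, 2.0]), azimuth_deg=0.0)
        ref = _plain_ref(np.zeros((3, 9)), np.zeros((3, 9)), anchor=(2.0, 2.0))
        p_h = locate_head_top(stack, plane, ref)
        # plane azimuth 0 -> u axis along y, anchored at u = anchor_y = 2.0
        assert p_h[0] == pytest.approx(4 * 0.5)          # pixel center
        assert p_h[1] == pytest.approx((1 - 0.5) * 0.5)  # interface above i0

    def test_two_runs_picks_longest_and_warns(self):
        data = np.zeros((2, 12, 12), bool)
        data[0, 2:4, 5] = True    # short run (rows 2..3)
        data[0, 6:11, 5] = True   # long run (rows 6..10)
        stack = MaskStack(data, (0.5, 0.5, 0.5))
        from tmjgap.reference_geometry import ReferencePlane
        plane = ReferencePlane(anchor=np.array([2.5, 2.5]), azimuth_deg=0.0)
        ref = _plain_ref(np.zeros((2, 12)), np.zeros((2, 12)), anchor=(2.5, 2.5))
        with pytest.warns(UserWarning, match="multiple"):
            p_h = locate_head_top(stack, plane, ref)
        assert p_h[0] == pytest.approx(8 * 0.5)  # midpoint of rows 6..10

    def test_plane_missing_mask_raises(self):
        data = np.zeros((2, 12, 12), bool)
        data[0, 2, 2] = True
        stack = MaskStack(data, (0.5, 0.5, 0.5))
        from tmjgap.reference_geometry import ReferencePlane
        plane = ReferencePlane(anchor=np.array([5.0, 5.0]), azimuth_deg=0.0)
        ref = _plain_ref(np.zeros((2, 12)), np.zeros((2, 12)))
        with pytest.raises(MeasurementError):
            locate_head_top(stack, plane, ref)


class TestLocateAcetabulum:
    def test_phantom_gap_recovered(self, sphere_run):
        p_h = locate_head_top(sphere_run.stack, sphere_run.plane, sphere_run.ref)
        p_a = locate_acetabulum_point(sphere_run.ref, p_h)
        spec, voi = sphere_run.spec, sphere_run.voi
        dz = spec.spacing[2]
        surface_v = spec.center[2] - spec.radius - spec.gap - voi.z_range[0] * dz
        assert p_a[1] == pytest.approx(surface_v, abs=dz)
        assert p_a[1] < p_h[1]

    def test_gap_intensity_irrelevant_given_mask(self):
        # soft-tissue vs air filling of the gap: same mask, same P_TMJa
        ref_soft, truth = circle_reference_slice(R=5, d=1.5, spacing=0.1)
        img_air = np.where(ref_soft.mask, 180.0, -950.0)
        ref_air = _plain_ref(img_air, ref_soft.mask, spacing=0.1,
                             bone_threshold=0.5 * (180 - 950))
        p_h = truth["p_top"]
        a = locate_acetabulum_point(ref_soft, p_h)
        b = locate_acetabulum_point(ref_air, p_h)
        assert a[0] == b[0]
        assert abs(a[1] - b[1]) <= 0.1  # sub-voxel refinement may differ

    def test_contact_case_raises(self):
        # head fused with the fossa: no gap anywhere above
        mask = np.zeros((20, 9), bool)
        mask[:15, 4] = True
        ref = _plain_ref(np.where(mask, 180.0, -60.0), mask)
        with pytest.raises(MeasurementError, match="acetabulum"):
            locate_acetabulum_point(ref, np.array([2.0, 14 * 0.5]))


def test_compute_rC_trivial_cases():
    p = np.array([3.0, 7.0])
    assert compute_rC(p, p + np.array([0.0, -3.0])) == pytest.approx(3.0)
    assert compute_rC(p, p) == 0.0


class TestLineProfile:
    def test_vertical_ramp_has_unit_slope(self):
        image = np.tile(np.arange(30)[:, None] * 0.5, (1, 20))  # value = v
        ref = _plain_ref(image, np.zeros_like(image))
        prof = line_profile(ref, (5.0, 1.0), 0.0, step=0.25)
        slope = np.polyfit(prof.positions, prof.values, 1)[0]
        assert slope == pytest.approx(1.0, abs=1e-9)

    def test_constant_image(self):
        ref = _plain_ref(np.full((20, 20), 7.0), np.zeros((20, 20)))
        prof = line_profile(ref, (3.0, 3.0), 30.0, step=0.2)
        assert np.allclose(prof.values, 7.0)

    def test_column_at_zero_angle_hits_pixel_centers(self):
        rng = np.random.default_rng(0)
        image = rng.normal(size=(25, 10))
        ref = _plain_ref(image, np.zeros_like(image))
        prof = line_profile(ref, (4 * 0.5, 0.0), 0.0, step=0.5)
        n = prof.values.size
        assert np.allclose(prof.values, image[:n, 4])


class TestFirstBoneEntry:
    def _step_profile(self, at=4.0, step=0.25, lo=-50.0, hi=200.0, noise=0.0,
                      seed=0):
        t = np.arange(0.0, 10.0, step)
        y = np.where(t < at, lo, hi).astype(float)
        if noise:
            y += np.random.default_rng(seed).normal(0, noise, y.size)
        return Profile(positions=t, values=y, origin=np.zeros(2),
                       direction=np.array([0.0, 1.0]))

    def test_step_located(self):
        prof = self._step_profile()
        assert first_bone_entry(prof) == pytest.approx(4.0, abs=0.125)

    def test_monotone_decreasing_gives_none(self):
        t = np.arange(0.0, 5.0, 0.25)
        prof = Profile(t, 100.0 - 10 * t, np.zeros(2), np.array([0.0, 1.0]))
        assert first_bone_entry(prof) is None

    def test_noisy_step_stable_over_realizations(self):
        hits = [first_bone_entry(self._step_profile(noise=10.0, seed=s))
                for s in range(100)]
        assert all(h is not None for h in hits)
        assert all(abs(h - 4.0) <= 2 * 0.25 for h in hits)

    def test_graze_bump_rejected_with_level(self):
        # a weak bump that never reaches bone level is not an entry
        t = np.arange(0.0, 10.0, 0.25)
        y = np.full(t.size, -60.0)
        y[20:28] = 30.0  # partial-volume bump, below the 60 threshold
        prof = Profile(t, y, np.zeros(2), np.array([0.0, 1.0]))
        assert first_bone_entry(prof) is not None
        assert first_bone_entry(prof, min_value=60.0) is None


class TestTangentSweep:
    def test_bracket_mean_rule(self):
        """A d(theta) series stepping between 31.0 and 31.5 degrees reports
        the tangent at the bracket mean, 31.25 degrees, exactly."""
        def d_fn(theta):
            return 3.0 / math.cos(math.radians(theta)) if theta <= 31.2 else None
        lo, hi, theta_T, _ = tangent_from_distance_fn(d_fn, SweepConfig())
        assert (lo, hi) == (31.0, 31.5)
        assert theta_T == 31.25

    def test_undefined_at_zero_raises(self):
        with pytest.raises(MeasurementError, match="d\\(0\\)"):
            tangent_from_distance_fn(lambda t: None, SweepConfig())

    def test_no_step_raises(self):
        with pytest.raises(MeasurementError, match="tangent not found"):
            tangent_from_distance_fn(
                lambda t: 3.0 + 0.01 * t, SweepConfig())

    def test_circle_matches_analytic_tangent(self):
        ref, truth = circle_reference_slice(R=6.0, d=2.0, spacing=0.05)
        expect = math.degrees(math.asin(6.0 / 8.0))
        for side in ("frontal", "dorsal"):
            tr = tangent_sweep(ref, truth["p_a"], side)
            assert tr.theta_T == pytest.approx(expect, abs=0.5)

    def test_distance_nondecreasing_before_step(self):
        ref, truth = circle_reference_slice(R=6.0, d=2.0, spacing=0.05)
        tr = tangent_sweep(ref, truth["p_a"], "frontal")
        coarse = sorted(t for t in tr.d_samples
                        if t % 5 == 0 and tr.d_samples[t] is not None
                        and t <= tr.theta_below)
        ds = [tr.d_samples[t] for t in coarse]
        assert all(b >= a for a, b in zip(ds, ds[1:]))

    def test_mirrored_slice_swaps_sides_exactly(self):
        ref, truth = circle_reference_slice(R=6.0, d=2.0, spacing=0.05,
                                            fossa_offset_u=1.0,
                                            noise_sigma=10.0, seed=3)
        res = {}
        for side in ("frontal", "dorsal"):
            tr = tangent_sweep(ref, truth["p_a"], side)
            r, _ = gap_width_at_tangent(ref, tr)
            res[side] = (tr.theta_T, r)
        ny = ref.image.shape[1]
        mref = _plain_ref(ref.image[:, ::-1], ref.mask[:, ::-1],
                          spacing=ref.du, bone_threshold=ref.bone_threshold)
        p_a_m = np.array([(ny - 1) * ref.du - truth["p_a"][0], truth["p_a"][1]])
        for side, other in (("frontal", "dorsal"), ("dorsal", "frontal")):
            tr = tangent_sweep(mref, p_a_m, side)
            r, _ = gap_width_at_tangent(mref, tr)
            assert (tr.theta_T, r) == res[other]


class TestGapWidth:
    def test_concentric_gap_both_sides(self):
        ref, truth = circle_reference_slice(R=6.0, d=2.0, spacing=0.05)
        for side in ("frontal", "dorsal"):
            tr = tangent_sweep(ref, truth["p_a"], side)
            r, p = gap_width_at_tangent(ref, tr)
            assert r == pytest.approx(2.0, abs=math.hypot(0.05, 0.05))

    def test_eccentric_fossa_matches_ray_cast(self):
        ref, truth = circle_reference_slice(R=6.0, d=2.0, spacing=0.05,
                                            fossa_offset_u=1.0)
        got = {}
        for side, sign in (("frontal", +1), ("dorsal", -1)):
            tr = tangent_sweep(ref, truth["p_a"], side)
            r, _ = gap_width_at_tangent(ref, tr)
            got[sign] = r
        assert got[-1] < got[+1]  # fossa shifted towards +u opens that side
        # half a voxel of the 0.3 mm CBCT grid the method targets
        assert got[+1] == pytest.approx(truth["r_u_plus"], abs=0.15)
        assert got[-1] == pytest.approx(truth["r_u_minus"], abs=0.15)

    def test_missing_shell_errors_on_that_side_only(self):
        ref, truth = circle_reference_slice(R=6.0, d=2.0, spacing=0.05,
                                            fossa_u_max=2.0)
        tr = tangent_sweep(ref, truth["p_a"], "dorsal")
        r, _ = gap_width_at_tangent(ref, tr)
        assert r == pytest.approx(2.0, abs=0.1)
        tr_f = tangent_sweep(ref, truth["p_a"], "frontal")
        with pytest.raises(MeasurementError, match="fossa not found"):
            gap_width_at_tangent(ref, tr_f)

    def test_gap_monotone_in_true_width(self):
        # R = 5 keeps arcsin(R / (R + d)) inside the 0-50 degree sweep for
        # all three gaps
        rs = []
        for d in (1.8, 2.4, 3.0):
            ref, truth = circle_reference_slice(R=5.0, d=d, spacing=0.05)
            tr = tangent_sweep(ref, truth["p_a"], "frontal")
            r, _ = gap_width_at_tangent(ref, tr)
            rs.append(r)
        assert rs[0] < rs[1] < rs[2]


class TestMeasureTMJ:
    def test_full_pipeline_recovers_phantom_gap(self, sphere_run):
        m = sphere_run.measurement
        g = sphere_run.spec.gap
        vox = sphere_run.spec.spacing[0]
        for r in (m.r_c_mm, m.r_d_mm, m.r_f_mm):
            assert abs(r - g) <= vox
        assert not any(m.degenerate.values())

    def test_deterministic_reports(self, sphere_run):
        m2 = measure_tmj(sphere_run.vol, sphere_run.voi, "left")
        import json
        assert json.dumps(m2.to_report(), sort_keys=True) == \
            json.dumps(sphere_run.measurement.to_report(), sort_keys=True)

    def test_laterality_swaps_side_labels(self, sphere_run):
        m_left = sphere_run.measurement
        m_right = measure_tmj(sphere_run.vol, sphere_run.voi, "right")
        assert m_right.r_d_mm == pytest.approx(m_left.r_f_mm)
        assert m_right.r_f_mm == pytest.approx(m_left.r_d_mm)

    def test_stage_errors_are_named(self):
        from tmjgap.errors import StageError
        from tmjgap.volume_io import VOIBox, Volume3D
        vol = Volume3D(np.zeros((10, 10, 10)), (0.3, 0.3, 0.3))
        with pytest.raises(StageError, match="crop_voi"):
            measure_tmj(vol, VOIBox((0, 20), (0, 10), (0, 10)), "left")
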