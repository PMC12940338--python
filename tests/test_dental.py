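"""Dental volumetrics: HMH segmentation, volumes, EDJ area, indices, VBI."""

import math

import numpy as np
import pytest

from paleomorph import dental
from paleomorph.dental import (
    DENTINE,
    ENAMEL,
    PULP,
    LabeledToothVolume,
    analyze_tooth,
    compute_volumes,
    edj_surface_area,
    enamel_indices,
    hmh_threshold,
    lateral_metrics,
    occlusal_basin_plane,
    segment_tissues,
    vbi_classify,
)
from paleomorph.synthetic import ShellToothSpec, make_gray_tooth, make_shell_tooth


class TestHMH:
    def test_midpoint_of_plateaus(self):
        assert hmh_threshold(20.0, 100.0) == pytest.approx(60.0)

    def test_equal_plateaus_rejected(self):
        with pytest.raises(ValueError, match="indistinguishable"):
            hmh_threshold(50.0, 50.0)

    def test_reversed_plateaus_rejected(self):
        with pytest.raises(ValueError):
            hmh_threshold(100.0, 20.0)


class TestSegmentation:
    def _thresholds(self):
        # HMH midpoints of the generator's default plateau levels
        return (
            hmh_threshold(0.0, 0.35),
            hmh_threshold(0.35, 0.65),
            hmh_threshold(0.65, 1.0),
        )

    def test_noiseless_recovers_ground_truth_exactly(self, shell_tooth_fine):
        lab, _ = shell_tooth_fine
        gray = make_gray_tooth(lab)
        seg = segment_tissues(
            gray, self._thresholds(), cervical_z=0.0,
            bifurcation_z=lab.bifurcation_z, origin_z=lab.origin_z,
        )
        assert np.array_equal(seg.labels, lab.labels)

    def test_noisy_segmentation_stays_at_interfaces(self, shell_tooth_fine):
        # 5%-of-contrast noise: every disagreement lies within the reach of
        # the median denoiser around a true interface, per-tissue volumes
        # stay within 2%, and the recovered enamel surface is within one
        # voxel of the analytic sphere
        lab, _ = shell_tooth_fine
        gray = make_gray_tooth(lab, noise_sd=0.05, seed=1)
        seg = segment_tissues(
            gray, self._thresholds(), cervical_z=0.0,
            bifurcation_z=lab.bifurcation_z, origin_z=lab.origin_z,
            denoise_median=3,
        )
        from scipy import ndimage

        diff = seg.labels != lab.labels
        boundary = np.zeros_like(diff)
        for code in (ENAMEL, DENTINE, PULP):
            m = lab.labels == code
            boundary |= m ^ ndimage.binary_erosion(m)
        band = ndimage.binary_dilation(boundary, np.ones((3, 3, 3), bool))
        assert not (diff & ~band).any()
        for code in (ENAMEL, DENTINE, PULP):
            n_true = (lab.labels == code).sum()
            n_seg = (seg.labels == code).sum()
            assert abs(n_seg / n_true - 1) < 0.02

        # interface localization: first enamel voxel along the +x axis
        # through the crown center vs the analytic outer radius
        nx, _, _ = lab.labels.shape
        iz = np.searchsorted(lab.z_centers, 2.0)  # a slice through the dome
        row_true = lab.labels[:, nx // 2, iz] == ENAMEL
        row_seg = seg.labels[:, nx // 2, iz] == ENAMEL
        assert abs(
            int(np.argmax(row_seg)) - int(np.argmax(row_true))
        ) <= 1

    def test_out_of_order_thresholds_rejected(self, shell_tooth_fine):
        lab, _ = shell_tooth_fine
        gray = make_gray_tooth(lab)
        with pytest.raises(ValueError, match="increasing"):
            segment_tissues(gray, (0.5, 0.2, 0.8), cervical_z=0.0,
                            bifurcation_z=-1.0)

    def test_empty_tissue_class_named(self, shell_tooth_fine):
        lab, _ = shell_tooth_fine
        gray = make_gray_tooth(lab)
        with pytest.raises(ValueError, match="enamel"):
            segment_tissues(gray, (0.2, 0.5, 5.0), cervical_z=0.0,
                            bifurcation_z=-1.0)


class TestVolumes:
    def test_shell_volumes_within_oracle_tolerance(self, shell_tooth_fine):
        lab, o = shell_tooth_fine
        v = compute_volumes(lab)
        for name in ("Ve", "Vcdp", "Vpc", "Vc", "Vcervix", "Vbranch", "Vt"):
            assert getattr(v, name) == pytest.approx(getattr(o, name), rel=0.02), name

    def test_volume_conservation_and_crown_partition(self, shell_tooth_fine):
        lab, _ = shell_tooth_fine
        v = compute_volumes(lab)
        vv = lab.voxel**3
        per_tissue = sum(
            (lab.labels == code).sum() * vv for code in (ENAMEL, DENTINE, PULP)
        )
        assert v.Vt == pytest.approx(per_tissue, rel=1e-12)
        assert v.Vc == pytest.approx(v.Ve + v.Vcdp, rel=1e-12)
        assert v.Vpc <= v.Vcdp

    def test_branch_volume_counts_only_below_bifurcation(self, shell_tooth_fine):
        lab, _ = shell_tooth_fine
        v = compute_volumes(lab)
        vv = lab.voxel**3
        below = (lab.z_centers < lab.bifurcation_z)[None, None, :]
        assert v.Vbranch == pytest.approx(
            ((lab.labels == PULP) & below).sum() * vv, rel=1e-12
        )


class TestEDJSurface:
    def test_hemispherical_edj_area(self, shell_tooth_fine):
        lab, o = shell_tooth_fine
        assert edj_surface_area(lab) == pytest.approx(o.SEDJ, rel=0.03)

    def test_planar_interface_area(self):
        # enamel slab over dentine slab, surrounded by background: the EDJ
        # is a flat square plane of known side length
        n, side, nz = 136, 128, 40
        lo = (n - side) // 2
        labels = np.zeros((n, n, nz), dtype=np.uint8)
        labels[lo : lo + side, lo : lo + side, 10:20] = DENTINE
        labels[lo : lo + side, lo : lo + side, 20:30] = ENAMEL
        lab = LabeledToothVolume(
            labels=labels, voxel=0.2, cervical_z=-10.0, bifurcation_z=-20.0,
            origin_z=0.0,
        )
        area = edj_surface_area(lab)
        assert area == pytest.approx((side * 0.2) ** 2, rel=0.02)

    def test_enamel_absent_rejected(self, shell_tooth_fine):
        lab, _ = shell_tooth_fine
        stripped = LabeledToothVolume(
            labels=np.where(lab.labels == ENAMEL, 0, lab.labels),
            voxel=lab.voxel, cervical_z=lab.cervical_z,
            bifurcation_z=lab.bifurcation_z, origin_z=lab.origin_z,
        )
        with pytest.raises(ValueError, match="enamel"):
            edj_surface_area(stripped)


class TestIndices:
    def test_average_enamel_thickness_arithmetic(self):
        aet, ret, pct = enamel_indices(Ve=100.0, SEDJ=50.0, Vcdp=1000.0, Vc=2000.0)
        assert aet == pytest.approx(2.0)
        assert ret == pytest.approx(100 * 2.0 / 10.0)
        assert pct == pytest.approx(50.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            enamel_indices(Ve=1.0, SEDJ=0.0, Vcdp=1.0, Vc=1.0)

    def test_scale_laws_under_isotropic_rescaling(self):
        # scaling every linear dimension by k multiplies AET by k and
        # leaves RET and the dentine proportion unchanged (2% tolerance)
        k = 1.35
        base = ShellToothSpec(voxel=0.1)
        scaled = ShellToothSpec(
            dentine_radius=base.dentine_radius * k,
            enamel_thickness=base.enamel_thickness * k,
            pulp_radius=base.pulp_radius * k,
            root_length=base.root_length * k,
            root_radius=base.root_radius * k,
            bifurcation_offset=base.bifurcation_offset * k,
            voxel=0.1,
        )
        lab1, o1 = make_shell_tooth(base)
        lab2, o2 = make_shell_tooth(scaled)
        m1 = analyze_tooth(lab1)
        m2 = analyze_tooth(lab2)
        assert m2.AET3D / m1.AET3D == pytest.approx(k, rel=0.02)
        assert m2.RET3D == pytest.approx(m1.RET3D, rel=0.02)
        assert m2.pctVcdp == pytest.approx(m1.pctVcdp, rel=0.02)
        # the scale-free oracle VBI is common to both phantoms; each
        # voxel-measured value stays within the voxelization tolerance
        assert o2.VBI == pytest.approx(o1.VBI, rel=1e-12)
        assert m1.VBI == pytest.approx(o1.VBI, rel=0.02)
        assert m2.VBI == pytest.approx(o2.VBI, rel=0.02)


class TestVBI:
    @pytest.mark.parametrize(
        "vbi,expected",
        [
            (0.0, "cynotaurodont"),
            (24.9, "cynotaurodont"),
            (25.0, "hypotaurodont"),
            (49.9, "hypotaurodont"),
            (50.0, "mesotaurodont"),
            (74.9, "mesotaurodont"),
            (75.0, "hypertaurodont"),
            (100.0, "hypertaurodont"),
        ],
    )
    def test_keene_band_edges(self, vbi, expected):
        value, cls = vbi_classify(vbi, 100.0 - vbi)
        assert value == pytest.approx(vbi)
        assert cls == expected

    def test_no_branch_canal_is_hypertaurodont(self):
        assert vbi_classify(30.0, 0.0) == (100.0, "hypertaurodont")

    def test_no_cervix_pulp_is_cynotaurodont(self):
        value, cls = vbi_classify(0.0, 80.0)
        assert value == 0.0 and cls == "cynotaurodont"

    def test_worked_example(self):
        value, cls = vbi_classify(20.0, 80.0)
        assert value == pytest.approx(20.0)
        assert cls == "cynotaurodont"

    def test_empty_pulp_system_rejected(self):
        with pytest.raises(ValueError):
            vbi_classify(0.0, 0.0)


class TestBasinAndLateral:
    def test_basin_plane_at_known_dimple_floor(self, dimple_tooth):
        lab, o = dimple_tooth
        plane = occlusal_basin_plane(lab)
        assert not plane.fallback
        assert abs(plane.z - o.basin_floor_z) <= lab.voxel

    def test_monotone_cap_falls_back(self, shell_tooth_fine):
        lab, _ = shell_tooth_fine
        assert occlusal_basin_plane(lab).fallback

    def test_lateral_slab_closed_forms(self, shell_tooth_fine):
        # below the hemisphere equator the enamel shell is a constant
        # annulus and the dentine a truncated hemisphere, so a lateral
        # plane at zb = 4 mm has closed-form slab volumes
        lab, _ = shell_tooth_fine
        zb = 4.0
        lat = lateral_metrics(lab, zb)
        spec = ShellToothSpec(voxel=0.15)
        R, t, p = spec.dentine_radius, spec.enamel_thickness, spec.pulp_radius
        lve = math.pi * ((R + t) ** 2 - R**2) * zb
        lvcdp = math.pi * (R**2 * zb - zb**3 / 3)
        lvpc = 2 / 3 * math.pi * p**3  # plane far above the pulp chamber
        assert lat.LVe == pytest.approx(lve, rel=0.02)
        assert lat.LVcdp == pytest.approx(lvcdp, rel=0.02)
        assert lat.LVpc == pytest.approx(lvpc, rel=0.02)
        # lateral EDJ is the spherical zone 2*pi*R*zb
        assert lat.LSEDJ == pytest.approx(2 * math.pi * R * zb, rel=0.03)

    def test_lateral_never_exceeds_whole_crown(self, dimple_tooth):
        lab, _ = dimple_tooth
        plane = occlusal_basin_plane(lab)
        lat = lateral_metrics(lab, plane.z)
        whole = compute_volumes(lab)
        assert lat.LVe <= whole.Ve
        assert lat.LVcdp <= whole.Vcdp
        assert lat.LVc <= whole.Vc

    def test_basin_above_crown_equals_whole_crown(self, shell_tooth_fine):
        lab, _ = shell_tooth_fine
        top = lab.z_centers[-1] + lab.voxel
        lat = lateral_metrics(lab, top)
        whole = compute_volumes(lab)
        assert lat.LVe == pytest.approx(whole.Ve, rel=1e-12)
        assert lat.LVcdp == pytest.approx(whole.Vcdp, rel=1e-12)
        assert lat.LSEDJ == pytest.approx(edj_surface_area(lab), rel=1e-9)

    def test_basin_below_cej_rejected(self, shell_tooth_fine):
        lab, _ = shell_tooth_fine
        with pytest.raises(ValueError, match="above"):
            lateral_metrics(lab, lab.cervical_z - 1.0)


class TestAnalyzeTooth:
    def test_full_workup_consistency(self, shell_tooth_fine):
        lab, o = shell_tooth_fine
        m = analyze_tooth(lab)
        assert m.AET3D == pytest.approx(m.Ve / m.SEDJ, rel=1e-12)
        assert m.VBI == pytest.approx(
            100 * m.Vcervix / (m.Vcervix + m.Vbranch), rel=1e-12
        )
        assert m.keene_class in dental.KEENE_CLASSES
        assert m.Ve == pytest.approx(o.Ve, rel=0.02)
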