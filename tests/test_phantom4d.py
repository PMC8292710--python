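import numpy as np
import pytest
from scipy import ndimage

from ventavoid import phantom4d as p4


class TestBuildReferenceAnatomy:
    def test_constructive(self, small_anatomy):
        assert small_anatomy.lung_mask.sum() > 0
        assert small_anatomy.tumor_mask.sum() > 0
        assert small_anatomy.airway_mask.sum() > 0
        for name in ("esophagus", "heart", "cord"):
            assert small_anatomy.oar_masks[name].sum() > 0

    def test_determinism(self):
        cfg = p4.PhantomConfig(shape=(48, 48, 48), spacing=(5.0, 5.0, 5.0))
        a = p4.build_reference_anatomy(cfg, seed=3)
        b = p4.build_reference_anatomy(cfg, seed=3)
        assert np.array_equal(a.grid.data, b.grid.data)
        assert np.array_equal(a.f_air, b.f_air)

    def test_f_air_bounds_clamped(self):
        cfg = p4.PhantomConfig(shape=(48, 48, 48), spacing=(5.0, 5.0, 5.0),
                               f_air_bounds=(0.3, 0.8))
        a = p4.build_reference_anatomy(cfg, seed=5)
        inside = a.f_air[a.f_air > 0]
        assert inside.min() >= 0.3 - 1e-12
        assert inside.max() <= 0.8 + 1e-12

    def test_masks_disjoint_and_inside_body(self, small_anatomy):
        a = small_anatomy
        assert not np.any(a.tumor_mask & a.airway_mask)
        assert not np.any(a.lung_mask & a.tumor_mask)
        for m in (a.lung_mask, a.tumor_mask, a.airway_mask, *a.oar_masks.values()):
            assert np.all(~m | a.body_mask)

    def test_f_air_zero_outside_lungs(self, small_anatomy):
        assert np.all(small_anatomy.f_air[~small_anatomy.lung_mask] == 0.0)
        inside = small_anatomy.f_air[small_anatomy.f_air > 0]
        assert np.all(inside < 1.0)

    def test_oversize_tumor_rejected(self):
        cfg = p4.PhantomConfig(shape=(48, 48, 48), spacing=(5.0, 5.0, 5.0),
                               tumor_radius_mm=80.0)
        with pytest.raises(ValueError, match="lung"):
            p4.build_reference_anatomy(cfg, seed=1)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="32"):
            p4.PhantomConfig(shape=(16, 48, 48))


class TestSynthesizeDvf:
    def test_zero_amplitude_is_identity(self, small_anatomy):
        dvf = p4.synthesize_dvf(small_anatomy, amplitude_mm=0.0, seed=11)
        assert np.all(dvf.vectors == 0.0)
        assert np.allclose(dvf.jacobian_determinant(), 1.0)

    def test_max_displacement_matches_amplitude(self, small_anatomy):
        dvf = p4.synthesize_dvf(small_anatomy, amplitude_mm=10.0, seed=11)
        assert np.max(dvf.magnitude()) == pytest.approx(10.0, abs=1e-9)

    def test_jacobian_positive(self, small_dvf):
        assert np.min(small_dvf.jacobian_determinant()) > 0.0

    def test_zero_outside_body(self, small_anatomy, small_dvf):
        outside = ~small_anatomy.body_mask
        assert np.max(small_dvf.magnitude()[outside]) < 1e-9

    def test_folding_amplitude_rejected(self, small_anatomy):
        with pytest.raises(ValueError, match="Jacobian"):
            p4.synthesize_dvf(small_anatomy, amplitude_mm=200.0, seed=11)

    def test_defect_factor_one_is_no_defect(self, small_anatomy):
        with_defect = p4.synthesize_dvf(small_anatomy, defect_factor=1.0, seed=11)
        # attenuation term vanishes: field equals the unattenuated profile
        j = with_defect.jacobian_determinant()
        a = small_anatomy
        dz0, dz1 = a.lung_third_bounds(a.config.defect_side, a.config.defect_third)
        z = a.grid.voxel_coordinates()[0]
        region = a.lung_masks[a.config.defect_side] & (z >= dz0) & (z <= dz1)
        other = a.lung_masks["left" if a.config.defect_side == "right" else "right"]
        # expansion inside the "defect" is comparable to the contralateral lung
        assert np.mean(j[region] - 1) > 0.3 * np.mean(j[other] - 1)

    def test_defect_attenuates_expansion(self, small_anatomy):
        full = p4.synthesize_dvf(small_anatomy, defect_factor=1.0, seed=11)
        damped = p4.synthesize_dvf(small_anatomy, defect_factor=0.05, seed=11)
        a = small_anatomy
        dz0, dz1 = a.lung_third_bounds(a.config.defect_side, a.config.defect_third)
        z = a.grid.voxel_coordinates()[0]
        region = a.lung_masks[a.config.defect_side] & (z >= dz0 + 15) & (z <= dz1 - 15)
        ratio = np.mean(damped.jacobian_determinant()[region] - 1) / np.mean(
            full.jacobian_determinant()[region] - 1
        )
        assert ratio < 0.35

    def test_analytic_jacobian_matches_finite_differences(self, small_anatomy,
                                                          small_dvf):
        from ventavoid.core import jacobian_from_gradient

        # fine-step central differences of the analytic field (h = 0.5 mm)
        pts = small_anatomy.grid.voxel_coordinates()[:, small_anatomy.lung_mask]
        h = 0.5
        grad = np.zeros((3, 3, pts.shape[1]))
        for comp in range(3):
            for axis in range(3):
                pp, pm = pts.copy(), pts.copy()
                pp[axis] += h
                pm[axis] -= h
                grad[comp, axis] = (small_dvf.u_fn(pp)[comp]
                                    - small_dvf.u_fn(pm)[comp]) / (2 * h)
        j_num = jacobian_from_gradient(grad)
        assert np.allclose(j_num, small_dvf.jacobian(pts), atol=2e-3)
        # grid-level finite differences agree up to truncation error
        j_fd = super(p4.PhantomDVF, small_dvf).jacobian_determinant()
        dev = np.abs(small_dvf.jacobian_determinant() - j_fd)
        assert dev[small_anatomy.lung_mask].max() < 0.02
        assert dev.max() < 0.15


class TestRenderPhase:
    def test_reference_phase_is_exact(self, small_anatomy, small_dvf):
        ph = p4.render_phase(small_anatomy, small_dvf, 0.0)
        lung = small_anatomy.f_air > 0
        assert np.allclose(ph.data[lung], -1000.0 * small_anatomy.f_air[lung])

    def test_tissue_conservation_pointwise(self, small_anatomy, small_dvf):
        # (1 - f_phase) * J_c == (1 - f_air) per exhale voxel
        a, dvf = small_anatomy, small_dvf
        mask = a.f_air > 0
        pts = a.grid.voxel_coordinates()[:, mask]
        for c in (0.3, 1.0):
            jc = 1.0 + c * dvf.jm1_fn(pts)
            f_phase = 1.0 - (1.0 - a.f_air[mask]) / jc
            assert np.allclose((1.0 - f_phase) * jc, 1.0 - a.f_air[mask], rtol=1e-12)

    def test_total_tissue_volume_conserved(self, small_anatomy, small_dvf):
        v0 = p4.total_tissue_volume(small_anatomy, small_dvf, 0.0)
        for c in (0.25, 0.5, 1.0):
            vc = p4.total_tissue_volume(small_anatomy, small_dvf, c)
            assert abs(vc - v0) / v0 < 1e-3

    def test_known_air_doubling_value(self):
        # J = 1.5 with f_air = 0.5: phase air fraction 2/3, HU = -666.67
        f_air, j = 0.5, 1.5
        f_phase = 1.0 - (1.0 - f_air) / j
        assert f_phase == pytest.approx(2.0 / 3.0)
        assert -1000.0 * f_phase == pytest.approx(-666.6667, abs=1e-3)

    def test_soft_tissue_unchanged(self, small_anatomy, small_dvf):
        ph0 = p4.render_phase(small_anatomy, small_dvf, 0.0)
        ph1 = p4.render_phase(small_anatomy, small_dvf, 1.0)
        # soft tissue voxels far from any moving interface keep their HU
        a = small_anatomy
        moving = a.lung_mask | a.airway_mask | a.tumor_mask
        for m in a.oar_masks.values():  # OAR boundaries advect too
            moving |= m
        static = a.body_mask & ~ndimage.binary_dilation(
            moving, iterations=int(np.ceil(8.0 / a.spacing[0])) + 2
        )
        mags = np.abs(ph1.data[static] - ph0.data[static])
        u_static = small_dvf.magnitude()[static]
        quiet = u_static < 0.1
        assert np.all(mags[quiet] < 1e-6)

    def test_invalid_phase_fraction(self, small_anatomy, small_dvf):
        with pytest.raises(ValueError, match="phase fraction"):
            p4.render_phase(small_anatomy, small_dvf, 1.5)


class TestGroundTruthVentilation:
    def test_identity_gives_zero(self, small_anatomy):
        dvf = p4.synthesize_dvf(small_anatomy, amplitude_mm=0.0, seed=11)
        vt = p4.ground_truth_ventilation(dvf, small_anatomy)
        assert np.all(vt.values[vt.valid] == 0.0)

    def test_air_doubling_worked_value(self):
        # J = 1.5, f_air = 0.5 -> ventilation 1.0 (air volume doubled)
        assert (1.5 - 1.0) / 0.5 == pytest.approx(1.0)

    def test_quarter_expansion_worked_value(self):
        assert (1.25 - 1.0) / 0.5 == pytest.approx(0.5)

    def test_airless_voxels_flagged(self, small_anatomy, small_dvf):
        vt = p4.ground_truth_ventilation(small_dvf, small_anatomy)
        vessels = small_anatomy.lung_mask & (small_anatomy.f_air == 0.0)
        assert vessels.sum() > 0
        assert not np.any(vt.valid[vessels])


class TestMake4DCT:
    def test_phase_count_and_extremes(self, small_4dct):
        assert small_4dct.n_phases == 10
        c = small_4dct.phase_fractions
        assert c[small_4dct.exhale_index] == pytest.approx(0.0, abs=1e-12)
        assert c[small_4dct.inhale_index] == pytest.approx(1.0, abs=1e-12)

    def test_tumor_centroid_excursion(self, small_4dct):
        sp = np.asarray(small_4dct.anatomy.spacing)
        c_ex = np.asarray(ndimage.center_of_mass(
            small_4dct.tumor_masks[small_4dct.exhale_index])) * sp
        c_in = np.asarray(ndimage.center_of_mass(
            small_4dct.tumor_masks[small_4dct.inhale_index])) * sp
        excursion = np.linalg.norm(c_in - c_ex)
        assert excursion == pytest.approx(6.0, abs=1.5 * sp[0])

    def test_determinism(self, small_anatomy, small_dvf):
        a = p4.make_4dct(small_anatomy, small_dvf)
        b = p4.make_4dct(small_anatomy, small_dvf)
        for pa, pb in zip(a.phases, b.phases):
            assert np.array_equal(pa.data, pb.data)

    def test_waveform_dwells_at_exhale(self):
        bc = p4.BreathingConfig(period_s=4.0, shape_power=2.0)
        t = np.linspace(0, 4.0, 1000, endpoint=False)
        c = np.asarray(bc.cycle_fraction(t))
        assert c.min() == pytest.approx(0.0, abs=1e-9)
        assert c.max() == pytest.approx(1.0, abs=1e-5)
        assert np.mean(c < 0.5) > 0.55  # longer dwell near exhale

    def test_start_phase_offsets_waveform(self):
        ex = p4.BreathingConfig(start_phase="max_exhale")
        inh = p4.BreathingConfig(start_phase="max_inhale")
        assert float(ex.cycle_fraction(0.0)) == pytest.approx(0.0, abs=1e-12)
        assert float(inh.cycle_fraction(0.0)) == pytest.approx(1.0, abs=1e-12)
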