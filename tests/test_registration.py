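"""Three-step pipeline: prealignment, affine, deformable, end-to-end."""

import numpy as np
import pytest

import histovar as hv
from histovar.evaluation import compute_tre
from histovar.ngf import NgfSettings, ngf_objective
from histovar.registration import (
    _gauss_newton,
    _pyramid_for,
    center_of_mass,
    rotation_angles,
)
from histovar.transforms import count_folds, promote

from conftest import EXTENT_UM, PREALIGN_SPACING_UM, SPACING_UM, desk_config, run_steps


class TestCenterOfMass:
    def test_point_mass(self):
        data = np.zeros((5, 5))
        data[2, 3] = 10.0
        np.testing.assert_allclose(center_of_mass(hv.Image(data, 1.0)), [3.0, 2.0])

    def test_constant_image_gives_geometric_center(self):
        np.testing.assert_allclose(
            center_of_mass(hv.Image(np.ones((4, 4)), 1.0)), [1.5, 1.5])

    def test_two_equal_masses_give_midpoint(self):
        data = np.zeros((3, 3))
        data[0, 0] = data[0, 2] = 5.0
        np.testing.assert_allclose(center_of_mass(hv.Image(data, 1.0)), [1.0, 0.0])

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError):
            center_of_mass(hv.Image(np.zeros((4, 4)), 1.0))


class TestRotationAngles:
    def test_quarter_turns(self):
        np.testing.assert_allclose(rotation_angles(4),
                                   [0, np.pi / 2, np.pi, 3 * np.pi / 2])

    def test_default_count_is_distinct_and_equispaced(self):
        a = rotation_angles(32)
        assert len(a) == 32
        assert len(np.unique(np.round(a % (2 * np.pi), 12))) == 32
        np.testing.assert_allclose(np.diff(a), 2 * np.pi / 32)
        assert a.max() < 2 * np.pi  # no duplicated endpoint

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            rotation_angles(1)


def _rigid_pair(seed, degrees, t_px=(8.0, -5.0)):
    spec = hv.SynthSpec(seed=seed)
    truth = hv.RigidTransform(np.deg2rad(degrees),
                              t_px[0] * SPACING_UM, t_px[1] * SPACING_UM,
                              (EXTENT_UM[0] / 2, EXTENT_UM[1] / 2))
    spec.deformation = truth
    return hv.make_pair(spec), truth


def _angle_diff_deg(a, b):
    return (np.rad2deg(a - b) + 180.0) % 360.0 - 180.0


class TestPrealign:
    def test_identical_images_recover_identity(self):
        sec = hv.make_pair(hv.SynthSpec(seed=30))
        ref = sec.reference
        cfg = desk_config()
        rp = _pyramid_for(ref, PREALIGN_SPACING_UM)
        rigid = hv.prealign(rp, rp, cfg.prealign, cfg.optimizer)
        assert abs(rigid.phi % (2 * np.pi)) < 1e-3 or \
            abs(rigid.phi % (2 * np.pi) - 2 * np.pi) < 1e-3
        assert np.hypot(rigid.t1, rigid.t2) < 0.1 * PREALIGN_SPACING_UM

    @pytest.mark.parametrize("degrees", [45.0, 170.0])
    def test_large_rotation_recovery(self, degrees):
        pair, truth = _rigid_pair(31, degrees)
        cfg = desk_config()
        rp = _pyramid_for(pair.reference, PREALIGN_SPACING_UM)
        tp = _pyramid_for(pair.template, PREALIGN_SPACING_UM)
        rigid = hv.prealign(rp, tp, cfg.prealign, cfg.optimizer)
        assert abs(_angle_diff_deg(rigid.phi, truth.phi)) < 1.0
        mid = np.array(EXTENT_UM) / 2
        err = np.linalg.norm(rigid.map_points(mid) - truth.map_points(mid))
        assert err < SPACING_UM  # within 1 px at generation resolution

    def test_result_not_worse_than_center_of_mass_alignment(self):
        pair, _ = _rigid_pair(32, 120.0)
        cfg = desk_config()
        rp = _pyramid_for(pair.reference, PREALIGN_SPACING_UM)
        tp = _pyramid_for(pair.template, PREALIGN_SPACING_UM)
        rigid = hv.prealign(rp, tp, cfg.prealign, cfg.optimizer)
        lv = rp.closest_level(PREALIGN_SPACING_UM)
        ref_l, tmpl_l = rp[lv], tp[lv]
        st = NgfSettings(cfg.prealign.epsilon)
        com_r = center_of_mass(ref_l)
        com_t = center_of_mass(tmpl_l)
        raw = hv.RigidTransform(0.0, *(com_t - com_r),
                                (float(com_r[0]), float(com_r[1])))
        assert ngf_objective(ref_l, tmpl_l, rigid, st) <= ngf_objective(
            ref_l, tmpl_l, raw, st) + 1e-12

    def test_translation_equivariance_whole_pixels(self):
        # pre-translating the template shifts the recovered translation by
        # exactly that amount and barely moves the rotation
        pair, truth = _rigid_pair(33, 40.0)
        cfg = desk_config()
        rp = _pyramid_for(pair.reference, PREALIGN_SPACING_UM)
        tp = _pyramid_for(pair.template, PREALIGN_SPACING_UM)
        base = hv.prealign(rp, tp, cfg.prealign, cfg.optimizer)

        shift_px = 6
        shifted = np.zeros_like(pair.template.data)
        shifted[:, shift_px:] = pair.template.data[:, :-shift_px]
        tp2 = _pyramid_for(hv.Image(shifted, SPACING_UM), PREALIGN_SPACING_UM)
        moved = hv.prealign(rp, tp2, cfg.prealign, cfg.optimizer)
        assert abs(_angle_diff_deg(moved.phi, base.phi)) < 0.5
        delta = np.array([moved.t1 - base.t1, moved.t2 - base.t2])
        np.testing.assert_allclose(delta, [shift_px * SPACING_UM, 0.0],
                                   atol=0.1 * SPACING_UM)


class TestRegisterAffine:
    def test_ground_truth_affine_recovery(self):
        spec = hv.SynthSpec(seed=5)
        c = np.array(EXTENT_UM) / 2
        th = np.deg2rad(10)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        mat = rot @ np.array([[1.1, 0.05], [0.0, 0.95]])
        truth = hv.AffineTransform(mat, c - mat @ c + np.array([8.0, -6.0]))
        spec.deformation = truth
        pair = hv.make_pair(spec)
        cfg = desk_config()
        rp = _pyramid_for(pair.reference, PREALIGN_SPACING_UM)
        tp = _pyramid_for(pair.template, PREALIGN_SPACING_UM)
        rigid = hv.prealign(rp, tp, cfg.prealign, cfg.optimizer)
        affine = hv.register_affine(rp, tp, rigid, cfg.affine, cfg.optimizer)
        pts = pair.reference.pixel_centers()[::8, ::8].reshape(-1, 2)
        err = np.linalg.norm(affine.map_points(pts) - truth.map_points(pts),
                             axis=1)
        assert err.mean() < 0.5 * SPACING_UM

    def test_no_progress_from_optimum_of_identical_pair(self):
        ref = hv.make_pair(hv.SynthSpec(seed=35)).reference
        st = NgfSettings(0.1)
        ident = hv.AffineTransform()
        v0 = ngf_objective(ref, ref, ident, st)
        opt, info = _gauss_newton(ref, ref, ident, st, 100, 1e-6, 1e-6)
        assert info["iterations"] <= 1
        assert info["final_objective"] == pytest.approx(v0, abs=1e-9)
        np.testing.assert_allclose(opt.get_parameters(), ident.get_parameters(),
                                   atol=1e-9)

    def test_default_epsilon_matches_pipeline_defaults(self):
        cfg = hv.RegistrationConfig()
        assert cfg.affine.epsilon == 0.1
        assert cfg.prealign.epsilon == 0.1
        assert cfg.prealign.n_levels == 4
        assert cfg.prealign.n_rotations == 32
        assert cfg.deformable.epsilon == 1.0
        assert cfg.deformable.alpha == 0.1
        assert cfg.deformable.grid_nodes == (257, 257)


class TestRegisterDeformable:
    def test_smooth_bump_recovery(self, restained_pair, restained_result):
        _, affine, grid, _ = restained_result
        mtre_affine = compute_tre(restained_pair.landmarks, affine).mtre_um
        mtre_def = compute_tre(restained_pair.landmarks, grid).mtre_um
        assert mtre_def < SPACING_UM  # < 1 px
        assert mtre_affine / mtre_def >= 5.0
        assert count_folds(grid) == 0  # default alpha keeps the map regular

    def test_huge_alpha_suppresses_curvature(self, restained_pair,
                                             restained_result):
        # the dominant-regularizer limit pins what curvature can see:
        # the returned map's curvature energy collapses by orders of
        # magnitude relative to the default-alpha solution (the data term
        # may still slide the grid within the penalty's near-null space
        # of affine / very smooth fields)
        from histovar.regularizer import curvature_energy_sampled

        cfg = desk_config()
        cfg.deformable.alpha = 1e6
        rp = _pyramid_for(restained_pair.reference, PREALIGN_SPACING_UM)
        tp = _pyramid_for(restained_pair.template, PREALIGN_SPACING_UM)
        rigid = hv.prealign(rp, tp, cfg.prealign, cfg.optimizer)
        affine = hv.register_affine(rp, tp, rigid, cfg.affine, cfg.optimizer)
        stiff = hv.register_deformable(rp, tp, affine, cfg.deformable,
                                       cfg.optimizer)
        default = restained_result[2]
        e_stiff = curvature_energy_sampled(stiff, rp[0])
        e_default = curvature_energy_sampled(default, rp[0])
        assert e_stiff < 1e-3 * e_default
        # and the map stays globally close to its affine initialization
        init = promote(affine, stiff.grid_shape, stiff.domain_extent,
                       stiff.origin)
        dev = np.abs(stiff.node_displacements - init.node_displacements)
        assert dev.max() < 3.0 * SPACING_UM


class TestPipeline:
    def test_identical_images_map_close_to_identity(self):
        ref = hv.make_pair(hv.SynthSpec(seed=36)).reference
        result = hv.run_pipeline(ref, ref, desk_config())
        pts = ref.pixel_centers()[::16, ::16].reshape(-1, 2)
        err = np.linalg.norm(result.deformable.map_points(pts) - pts, axis=1)
        assert err.max() < 0.1 * SPACING_UM
        assert result.diagnostics["fold_count"] == 0

    def test_per_step_mtre_is_monotone(self, restained_pair, restained_result):
        rigid, affine, grid, _ = restained_result
        lms = restained_pair.landmarks
        m1 = compute_tre(lms, rigid).mtre_um
        m2 = compute_tre(lms, affine).mtre_um
        m3 = compute_tre(lms, grid).mtre_um
        assert m1 >= m2 >= m3

    def test_restained_beats_consecutive(self, restained_pair, restained_result,
                                         consecutive_pair, consecutive_result):
        m_re = compute_tre(restained_pair.landmarks, restained_result[2]).mtre_um
        m_co = compute_tre(consecutive_pair.landmarks,
                           consecutive_result[2]).mtre_um
        assert m_re < m_co
        assert m_re < 1.0 * SPACING_UM  # restained-like: < 1 px
        assert m_co < 2.0 * SPACING_UM  # consecutive-like: < 2 px

    def test_bit_identical_reruns(self, restained_pair):
        r1 = hv.run_pipeline(restained_pair.reference, restained_pair.template,
                             desk_config())
        r2 = hv.run_pipeline(restained_pair.reference, restained_pair.template,
                             desk_config())
        assert hv.transform_to_json(r1.rigid) == hv.transform_to_json(r2.rigid)
        assert hv.transform_to_json(r1.affine) == hv.transform_to_json(r2.affine)
        assert hv.transform_to_json(r1.deformable) == hv.transform_to_json(
            r2.deformable)

    def test_records_distances_and_diagnostics(self, restained_pair):
        result = hv.run_pipeline(restained_pair.reference,
                                 restained_pair.template, desk_config())
        for step in ("prealign", "affine", "deformable"):
            assert result.per_step_distance[step] >= 0.0
        assert result.per_step_distance["deformable"] <= \
            result.per_step_distance["affine"] * 1.5  # different eps scales
        assert result.diagnostics["fold_count"] >= 0


class TestResolutionSweep:
    def test_sweep_on_nonlinear_pair(self, restained_pair):
        table = hv.resolution_sweep(
            restained_pair.reference, restained_pair.template,
            restained_pair.landmarks, [4.0, 16.0], desk_config())
        assert list(table["spacing_um"]) == [16.0, 4.0]
        fine = table[table.spacing_um == 4.0].iloc[0]
        # deformable beats affine at fine spacing (ratio > 1)
        assert fine.affine_deformable_ratio > 1.0
        # finest deformable MTRE <= coarsest deformable MTRE
        coarse = table[table.spacing_um == 16.0].iloc[0]
        assert fine.mtre_deformable_um <= coarse.mtre_deformable_um
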