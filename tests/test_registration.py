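"""NCC correctness, affine resampling, parameter recovery and reference
ranking on phantoms with known ground truth."""
import numpy as np
import pytest

from atlasforge.errors import RegistrationFailureError, ZeroVarianceError
from atlasforge.grids import BinaryMask, VolumeGrid
from atlasforge.registration import (
    AffineTransform,
    CalibrationSet,
    CalibrationSpecimen,
    Scan,
    affine_register,
    apply_affine,
    ncc,
    rank_reference_candidates,
    _params_to_transform,
)
from atlasforge.synthetic_data import PhantomSpec, make_calibration_set, make_reference_brain

from conftest import smooth_random_volume


class TestNCC:
    def test_self_correlation_is_one(self, rng):
        x = VolumeGrid(rng.uniform(0, 1, (8, 8, 8)))
        assert ncc(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelation_is_minus_one(self, rng):
        x = VolumeGrid(rng.uniform(0, 1, (8, 8, 8)))
        y = VolumeGrid(2.0 - x.data)
        assert ncc(x, y) == pytest.approx(-1.0, abs=1e-12)

    def test_masked_ncc_equals_bruteforce_extraction(self, rng):
        """Oracle: Pearson r of the mask-extracted voxel lists via np.corrcoef."""
        for _ in range(10):
            a = VolumeGrid(rng.uniform(0, 1, (16, 16, 16)))
            b = VolumeGrid(rng.uniform(0, 1, (16, 16, 16)))
            m = BinaryMask(rng.uniform(size=(16, 16, 16)) < 0.3)
            expected = np.corrcoef(a.data[m.data], b.data[m.data])[0, 1]
            assert ncc(a, b, m) == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_positive_affine_intensity_rescaling(self, rng):
        a = VolumeGrid(rng.uniform(0, 1, (8, 8, 8)))
        b = VolumeGrid(rng.uniform(0, 1, (8, 8, 8)))
        base = ncc(a, b)
        assert abs(ncc(VolumeGrid(2.5 * a.data + 0.3), b) - base) < 1e-9
        assert abs(ncc(a, VolumeGrid(0.04 * b.data + 7.0)) - base) < 1e-9

    def test_symmetry(self, rng):
        a = VolumeGrid(rng.uniform(0, 1, (6, 6, 6)))
        b = VolumeGrid(rng.uniform(0, 1, (6, 6, 6)))
        assert ncc(a, b) == pytest.approx(ncc(b, a), abs=1e-14)

    def test_zero_variance_raises_not_zero(self):
        a = VolumeGrid(np.ones((4, 4, 4)))
        b = VolumeGrid(np.random.default_rng(0).uniform(0, 1, (4, 4, 4)))
        with pytest.raises(ZeroVarianceError):
            ncc(a, b)


class TestAffineTransform:
    def test_dof6_requires_orthonormal_linear_part(self):
        m = np.hstack([np.diag([1.1, 1.0, 1.0]), np.zeros((3, 1))])
        with pytest.raises(ValueError):
            AffineTransform(m, dof=6)
        AffineTransform(m, dof=12)  # fine as a full affine

    def test_inverse_compose_is_identity(self, rng):
        m = np.hstack([np.eye(3) + 0.1 * rng.standard_normal((3, 3)),
                       rng.standard_normal((3, 1))])
        t = AffineTransform(m)
        ident = t.compose(t.inverse())
        np.testing.assert_allclose(ident.linear, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(ident.translation, 0.0, atol=1e-9)

    def test_json_round_trip(self, tmp_path):
        t = _params_to_transform(np.array([1, -2, 3, 4, 0, -5, 0.01, 0, 0, 0, 0, 0.]),
                                 12, np.zeros(3), np.zeros(3))
        path = tmp_path / "t.json"
        t.save(path, spacing=(1, 1, 2))
        back = AffineTransform.load(path)
        np.testing.assert_allclose(back.matrix, t.matrix)
        assert back.dof == t.dof


class TestApplyAffine:
    def test_identity_on_same_grid_is_identity(self, rng):
        v = VolumeGrid(rng.uniform(0, 1, (8, 10, 6)), (1, 1, 2))
        out = apply_affine(v, AffineTransform.identity(), interp="trilinear")
        np.testing.assert_allclose(out.data, v.data, atol=1e-12)

    def test_integer_voxel_translation_nearest_is_exact_shift(self, rng):
        """Index-shift oracle: translating by whole voxels with nearest
        interpolation must reproduce an array roll with zero fill."""
        v = VolumeGrid(rng.uniform(0.1, 1, (8, 10, 6)), (1, 1, 2))
        shift_vox = np.array([2, -3, 1])
        shift_um = shift_vox * np.asarray(v.spacing)
        t = AffineTransform(np.hstack([np.eye(3), shift_um[:, None]]))
        out = apply_affine(v, t, interp="nearest")
        expected = np.zeros_like(v.data)
        expected[2:, :7, 1:] = v.data[:6, 3:, :5]
        np.testing.assert_array_equal(out.data, expected)

    def test_warped_mask_stays_binary(self):
        m = np.zeros((8, 8, 8))
        m[2:5, 3:6, 1:4] = 1.0
        v = VolumeGrid(m)
        p = np.array([0.7, -1.3, 0.4, 5.0, -3.0, 8.0, 0, 0, 0, 0, 0, 0.])
        t = _params_to_transform(p, 6, np.full(3, 4.0), np.full(3, 4.0))
        out = apply_affine(v, t, interp="nearest")
        assert set(np.unique(out.data)) <= {0.0, 1.0}


@pytest.fixture(scope="module")
def reg_spec():
    return PhantomSpec(shape=(40, 64, 28), spacing=(2.0, 2.0, 4.0),
                       semi_axes=(36.0, 60.0, 50.0), seed=13)


@pytest.fixture(scope="module")
def reg_brain(reg_spec):
    return make_reference_brain(reg_spec)[0]


class TestAffineRegister:
    def test_self_registration_stays_near_identity(self, reg_brain):
        t = affine_register(reg_brain, reg_brain, dof=6, levels=2, min_step=0.5)
        assert t.rotation_angle_deg() < 0.5
        center = np.asarray(reg_brain.shape) * np.asarray(reg_brain.spacing) / 2
        assert np.linalg.norm(t.apply_points(center) - center) < 1.0  # < 0.5 voxel

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_parameter_recovery(self, reg_spec, reg_brain, seed):
        """Rotate 7 deg about z and translate (4, -3, 2) voxels (plus seeded
        variants): recovered within 1 deg and 1 voxel."""
        r = np.random.default_rng(seed)
        p = np.zeros(12)
        p[:3] = [8.0, -6.0, 8.0] if seed == 0 else r.uniform(-8, 8, 3)
        p[5] = 7.0 if seed == 0 else r.uniform(-7, 7)
        c = reg_spec.center
        truth = _params_to_transform(p, 6, c, c)
        floating = apply_affine(reg_brain, truth.inverse())
        rec = affine_register(floating, reg_brain, dof=6, levels=3, min_step=0.5)
        delta = rec.compose(truth.inverse())
        assert delta.rotation_angle_deg() < 1.0
        assert np.linalg.norm(delta.apply_points(c) - c) < 2.0  # 1 voxel = 2 um

    def test_scale_recovery_dof12(self, reg_spec, reg_brain):
        p = np.zeros(12)
        p[7] = np.log(1.05)  # 5% stretch along y
        c = reg_spec.center
        truth = _params_to_transform(p, 12, c, c)
        floating = apply_affine(reg_brain, truth.inverse())
        rec = affine_register(floating, reg_brain, dof=12, levels=3, min_step=0.5)
        y_scale = np.linalg.norm(rec.linear[:, 1])
        assert y_scale == pytest.approx(1.05, abs=0.01)

    def test_monotone_improvement_over_identity(self, reg_spec, reg_brain):
        p = np.zeros(12)
        p[:3] = [4.0, 6.0, -4.0]
        p[4] = 4.0
        truth = _params_to_transform(p, 6, reg_spec.center, reg_spec.center)
        floating = apply_affine(reg_brain, truth.inverse())
        t = affine_register(floating, reg_brain, dof=6, levels=3, min_step=0.5)
        warped = apply_affine(floating, t, reg_brain.shape, reg_brain.spacing)
        assert ncc(warped, reg_brain) >= ncc(floating, reg_brain)

    def test_constant_volume_fails_cleanly(self):
        flat = VolumeGrid(np.ones((8, 8, 8)))
        tex = smooth_random_volume((8, 8, 8), (1, 1, 1), seed=3)
        with pytest.raises(RegistrationFailureError):
            affine_register(flat, tex)


@pytest.fixture(scope="module")
def tiny_cal():
    spec = PhantomSpec(shape=(32, 48, 20), spacing=(2.5, 2.5, 5.0),
                       semi_axes=(32.0, 50.0, 40.0),
                       jitter_rot_deg=3.0, jitter_trans_um=4.0,
                       noise_sigma=0.02, seed=21)
    brain, _ = make_reference_brain(spec)
    cal = make_calibration_set(brain, n_specimens=1, spec=spec)
    return spec, brain, cal


class TestRankReferences:
    def test_single_candidate_single_specimen(self, tiny_cal):
        spec, brain, cal = tiny_cal
        table = rank_reference_candidates([brain], cal, levels=2, min_step=1.0)
        assert table.rank == [1]
        assert table.best == "candidate0"
        assert -1.0 <= table.reference_ncc_mean[0] <= 1.0

    def test_identical_candidates_tie_broken_by_input_order(self, tiny_cal):
        spec, brain, cal = tiny_cal
        table = rank_reference_candidates([brain, brain], cal, levels=2, min_step=1.0,
                                          candidate_ids=["first", "second"])
        assert table.reference_ncc_mean[0] == pytest.approx(table.reference_ncc_mean[1],
                                                            abs=1e-9)
        assert table.rank == [1, 2]
        frame = table.to_frame()
        assert list(frame["candidate"]) == ["first", "second"]
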