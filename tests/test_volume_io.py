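"""Volume I/O and stack conditioning: normalization, unmixing, stitching,
resampling, attenuation correction, and disk round-trips."""
import numpy as np
import pytest

from atlasforge.errors import DegenerateInputError, GridMismatchError, StitchFailureError
from atlasforge.grids import VolumeGrid
from atlasforge.volume_io import (
    MixingMatrix,
    correct_z_attenuation,
    estimate_z_attenuation,
    normalize_saturate,
    read_volume,
    resample_isotropic,
    stitch_pair,
    unmix_channels,
    write_volume,
)

from conftest import smooth_random_volume


class TestNormalizeSaturate:
    def test_exactly_one_voxel_saturates_on_distinct_values(self, rng):
        """With fraction 1e-4 on 10^4 distinct values, only the max clips to 1."""
        values = rng.permutation(np.linspace(0.1, 5.0, 10_000))
        v = VolumeGrid(values.reshape(10, 100, 10))
        out = normalize_saturate(v, fraction=1e-4)
        assert (out.data == 1.0).sum() == 1
        assert out.data.max() == 1.0
        # sort-based oracle: the saturation quantile lies between the two
        # largest values, so every non-max voxel stays strictly below 1
        s = np.sort(values)
        q = np.quantile(values, 1 - 1e-4)
        assert s[-2] < q <= s[-1]

    def test_constant_volume_maps_to_all_ones(self):
        v = VolumeGrid(np.full((4, 5, 6), 3.7))
        out = normalize_saturate(v, fraction=0.01)
        assert np.all(out.data == 1.0)

    def test_fraction_zero_divides_by_max(self, rng):
        v = VolumeGrid(rng.uniform(0, 9, size=(6, 6, 6)))
        out = normalize_saturate(v, fraction=0.0)
        np.testing.assert_allclose(out.data, v.data / v.data.max())

    def test_idempotent_after_first_application(self, rng):
        v = VolumeGrid(rng.uniform(0, 2, size=(8, 8, 8)))
        once = normalize_saturate(v, 1e-3)
        twice = normalize_saturate(once, 1e-3)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_ordering_of_subquantile_intensities_preserved(self, rng):
        v = VolumeGrid(rng.uniform(0, 1, size=(10, 10, 10)))
        out = normalize_saturate(v, 0.01)
        below = out.data < 1.0
        order_in = np.argsort(v.data[below], kind="stable")
        order_out = np.argsort(out.data[below], kind="stable")
        np.testing.assert_array_equal(order_in, order_out)

    def test_all_zero_volume_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalize_saturate(VolumeGrid(np.zeros((3, 3, 3))), 1e-4)

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            normalize_saturate(VolumeGrid(np.ones((3, 3, 3))), 1.0)


class TestUnmix:
    def test_identity_matrix_returns_inputs(self, rng):
        a = VolumeGrid(rng.uniform(0, 1, (5, 5, 5)))
        b = VolumeGrid(rng.uniform(0, 1, (5, 5, 5)))
        ua, ub = unmix_channels(a, b, MixingMatrix(((1, 0), (0, 1))))
        np.testing.assert_allclose(ua.data, a.data)
        np.testing.assert_allclose(ub.data, b.data)

    def test_forward_mix_then_unmix_recovers_abundances(self, rng):
        """Cross-talk inversion: mix with known coefficients, recover to 1e-6."""
        a = rng.uniform(0, 1, (6, 6, 6))
        b = rng.uniform(0, 1, (6, 6, 6))
        m = MixingMatrix(((1.0, 0.2), (0.1, 1.0)))
        mixed_a = VolumeGrid(1.0 * a + 0.2 * b)
        mixed_b = VolumeGrid(0.1 * a + 1.0 * b)
        ua, ub = unmix_channels(mixed_a, mixed_b, m)
        np.testing.assert_allclose(ua.data, a, atol=1e-6)
        np.testing.assert_allclose(ub.data, b, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_unmix_inverts_forward_mix_for_random_invertible_matrices(self, seed):
        r = np.random.default_rng(seed)
        while True:
            coef = r.uniform(0, 0.6, size=(2, 2)) + np.eye(2)
            if abs(np.linalg.det(coef)) > 0.1:
                break
        m = MixingMatrix(tuple(map(tuple, coef)))
        a = r.uniform(0, 1, (4, 4, 4))
        b = r.uniform(0, 1, (4, 4, 4))
        det = coef[0, 0] * a + coef[0, 1] * b, coef[1, 0] * a + coef[1, 1] * b
        ua, ub = unmix_channels(VolumeGrid(det[0]), VolumeGrid(det[1]), m)
        np.testing.assert_allclose(ua.data, a, atol=1e-9)
        np.testing.assert_allclose(ub.data, b, atol=1e-9)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            MixingMatrix(((1, 1), (1, 1)))

    def test_grid_mismatch_rejected(self):
        a = VolumeGrid(np.ones((4, 4, 4)))
        b = VolumeGrid(np.ones((4, 4, 5)))
        with pytest.raises(GridMismatchError):
            unmix_channels(a, b, MixingMatrix(((1, 0), (0, 1))))


class TestStitch:
    @pytest.mark.parametrize("dy,dx,dz", [(28, 0, 0), (30, 1, -1), (25, -2, 2)])
    def test_offset_recovered_exactly_on_noiseless_split(self, dy, dx, dz):
        """Split a textured volume into overlapping tiles at a known shift."""
        whole = smooth_random_volume((40, 64, 24), (1, 1, 2), seed=4)
        rostral = VolumeGrid(whole.data[:, :40, :], whole.spacing)
        lo = np.array([dx, dy, dz])
        caudal = VolumeGrid(
            whole.data[max(lo[0], 0):, lo[1]:, max(lo[2], 0):][
                : 40 - abs(dx), :, : 24 - abs(dz)
            ],
            whole.spacing,
        )
        # caudal tile content starts at (max(dx,0), dy, max(dz,0)) of the whole;
        # its offset relative to the rostral tile origin is exactly that
        expect = (max(dx, 0), dy, max(dz, 0))
        offset, fused, score = stitch_pair(rostral, caudal, (3, 34, 3))
        assert offset == expect
        assert score > 0.999

    def test_identical_tiles_zero_offset_and_verbatim_fusion(self):
        v = smooth_random_volume((16, 20, 10), (1, 1, 2), seed=5)
        offset, fused, score = stitch_pair(v, v, 0)
        assert offset == (0, 0, 0)
        np.testing.assert_allclose(fused.data, v.data, atol=1e-9)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_nonoverlap_regions_copied_verbatim(self):
        whole = smooth_random_volume((16, 48, 10), (1, 1, 2), seed=6)
        rostral = VolumeGrid(whole.data[:, :30, :], whole.spacing)
        caudal = VolumeGrid(whole.data[:, 20:, :], whole.spacing)
        offset, fused, _ = stitch_pair(rostral, caudal, (0, 24, 0))
        assert offset == (0, 20, 0)
        np.testing.assert_allclose(fused.data, whole.data, atol=1e-9)
        np.testing.assert_array_equal(fused.data[:, :20, :], rostral.data[:, :20, :])
        np.testing.assert_array_equal(fused.data[:, 30:, :], caudal.data[:, 10:, :])

    def test_pure_noise_reports_low_ncc(self):
        r1 = np.random.default_rng(1).uniform(0.1, 1, (12, 20, 8))
        r2 = np.random.default_rng(2).uniform(0.1, 1, (12, 20, 8))
        _, _, score = stitch_pair(VolumeGrid(r1), VolumeGrid(r2), (0, 6, 0))
        assert score < 0.5  # caller can reject an implausible stitch

    def test_insufficient_overlap_raises(self):
        a = VolumeGrid(np.random.default_rng(0).uniform(0.1, 1, (8, 6, 8)))
        with pytest.raises(StitchFailureError):
            stitch_pair(a, a, (0, 0, 0))  # only 6 y-voxels available


class TestResample:
    def test_identity_when_already_isotropic(self, rng):
        v = VolumeGrid(rng.uniform(0, 1, (6, 6, 6)), (1.5, 1.5, 1.5))
        out = resample_isotropic(v, 1.5)
        np.testing.assert_array_equal(out.data, v.data)

    def test_constant_stays_constant(self):
        v = VolumeGrid(np.full((5, 5, 5), 2.0), (1, 1, 2))
        out = resample_isotropic(v, 1.0)
        np.testing.assert_allclose(out.data, 2.0)
        assert out.shape == (5, 5, 9)

    def test_linear_ramp_halves_increment_and_keeps_endpoints(self):
        """Closed form: a z-ramp at spacing 2 resampled to 1 keeps endpoints."""
        ramp = np.tile(np.arange(8, dtype=float) * 2.0, (4, 4, 1))
        v = VolumeGrid(ramp, (1, 1, 2))
        out = resample_isotropic(v, 1.0)
        assert out.shape[2] == 15
        np.testing.assert_allclose(out.data[0, 0, :], np.arange(15, dtype=float), atol=1e-6)

    def test_round_trip_within_interpolation_tolerance(self):
        v = smooth_random_volume((20, 20, 12), (2, 2, 2), seed=9)
        back = resample_isotropic(resample_isotropic(v, 1.0), 2.0)
        assert back.shape == v.shape
        err = np.abs(back.data - v.data).max()
        assert err < 0.02 * (v.data.max() - v.data.min())


class TestAttenuation:
    def test_estimates_known_decay_coefficient(self, brain):
        decayed = correct_z_attenuation(brain, 0.0)  # copy via no-op
        z = np.arange(brain.shape[2]) * brain.spacing[2]
        decayed = brain.with_data(brain.data * np.exp(-0.004 * z)[None, None, :])
        c = estimate_z_attenuation(decayed, brain)
        assert c == pytest.approx(0.004, rel=0.15)

    def test_correction_inverts_known_decay(self, brain):
        z = np.arange(brain.shape[2]) * brain.spacing[2]
        decayed = brain.with_data(brain.data * np.exp(-0.003 * z)[None, None, :])
        restored = correct_z_attenuation(decayed, 0.003)
        np.testing.assert_allclose(restored.data, brain.data, atol=1e-9)

    def test_no_decay_estimates_near_zero(self, brain):
        assert estimate_z_attenuation(brain, brain) == pytest.approx(0.0, abs=1e-9)


class TestDiskRoundTrip:
    @pytest.mark.parametrize("name", ["vol.nii", "vol.nii.gz", "vol.tif"])
    def test_write_read_preserves_data_and_spacing(self, tmp_path, rng, name):
        v = VolumeGrid(rng.uniform(0, 1, (6, 7, 8)).astype(np.float32).astype(float),
                       (1.0, 1.0, 2.0))
        path = tmp_path / name
        write_volume(v, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.data, v.data, atol=1e-6)
        np.testing.assert_allclose(back.spacing, v.spacing, rtol=1e-5)
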