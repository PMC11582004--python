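"""Local SBR rescaling, striatal mask construction, mirroring, summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from datlearn import behavior, spect, synthetic
from datlearn.spect import (
    Mask,
    Volume,
    build_datstriatum_mask,
    mirror_volume,
    occipital_mask,
    rescale_local_sbr,
    restrict_hemisphere,
    striatal_summary,
    voxel_to_mni,
)


def _grid(shape=(10, 10, 10), vox=2.0):
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = -vox * (np.array(shape) - 1) / 2.0  # symmetric about 0
    return affine


@pytest.fixture
def occ_setup():
    shape = (10, 10, 10)
    affine = _grid(shape)
    occ = np.zeros(shape, bool)
    occ[:, :2, :] = True
    return shape, affine, Mask(occ, affine, "test occipital")


class TestRescaleLocalSbr:
    def test_unit_reference_passes_values_through(self, occ_setup):
        shape, affine, occ = occ_setup
        data = np.ones(shape)
        data[5, 5, 5] = 2.4
        out = rescale_local_sbr(Volume(data, affine), occ)
        assert out.data[5, 5, 5] == pytest.approx(2.4)

    def test_scale_invariance(self, occ_setup, rng):
        shape, affine, occ = occ_setup
        data = rng.uniform(0.5, 3.0, size=shape)
        a = rescale_local_sbr(Volume(data, affine), occ)
        b = rescale_local_sbr(Volume(7.3 * data, affine), occ)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_non_unit_reference(self, occ_setup):
        shape, affine, occ = occ_setup
        data = np.zeros(shape)
        data[occ.data] = 0.8
        data[5, 5, 5] = 2.0
        out = rescale_local_sbr(Volume(data, affine), occ)
        assert out.data[5, 5, 5] == pytest.approx(2.5)

    def test_idempotent(self, occ_setup, rng):
        shape, affine, occ = occ_setup
        vol = Volume(rng.uniform(0.5, 3.0, size=shape), affine)
        once = rescale_local_sbr(vol, occ)
        twice = rescale_local_sbr(once, occ)
        np.testing.assert_allclose(once.data, twice.data, rtol=1e-12)
        assert once.data[occ.data].mean() == pytest.approx(1.0)

    def test_nonpositive_reference_rejected(self, occ_setup):
        shape, affine, occ = occ_setup
        with pytest.raises(ValueError, match="positive"):
            rescale_local_sbr(Volume(np.zeros(shape), affine), occ)


class TestDatstriatumMask:
    def test_threshold_boundary_inclusive(self):
        affine = _grid((4, 4, 4))
        data = np.full((4, 4, 4), 1.0)
        data[0, 0, 0] = 2.0
        data[1, 1, 1] = 1.999
        mask = build_datstriatum_mask([Volume(data, affine)], threshold=2.0)
        assert mask.data[0, 0, 0]
        assert not mask.data[1, 1, 1]

    def test_matches_voxelwise_threshold_oracle(self, rng):
        affine = _grid((8, 8, 8))
        vols = [Volume(rng.uniform(0.0, 4.0, size=(8, 8, 8)), affine) for _ in range(5)]
        mask = build_datstriatum_mask(vols, threshold=2.0)
        mean = sum(v.data for v in vols) / 5.0
        oracle = np.array(
            [[[mean[i, j, k] >= 2.0 for k in range(8)] for j in range(8)] for i in range(8)]
        )
        np.testing.assert_array_equal(mask.data, oracle)

    def test_raising_threshold_never_adds_voxels(self, rng):
        affine = _grid((8, 8, 8))
        vols = [Volume(rng.uniform(0.0, 4.0, size=(8, 8, 8)), affine) for _ in range(4)]
        lo = build_datstriatum_mask(vols, threshold=1.5)
        hi = build_datstriatum_mask(vols, threshold=2.5)
        assert not (hi.data & ~lo.data).any()

    def test_geometry_mismatch_rejected(self):
        a = Volume(np.ones((4, 4, 4)), _grid((4, 4, 4)))
        b = Volume(np.ones((5, 5, 5)), _grid((5, 5, 5)))
        with pytest.raises(ValueError, match="grid"):
            build_datstriatum_mask([a, b])


class TestMirrorVolume:
    def test_peak_reflects_across_midline(self):
        shape = (15, 11, 11)
        affine = _grid(shape, vox=4.0)
        data = np.zeros(shape)
        ijk = np.round(spect.mni_to_voxel(affine, [-28.0, 0.0, 6.0])).astype(int)
        data[tuple(ijk)] = 5.0
        out = mirror_volume(Volume(data, affine))
        peak = np.unravel_index(np.argmax(out.data), shape)
        assert voxel_to_mni(affine, np.array(peak))[0] == pytest.approx(28.0)

    def test_involution_bit_exact(self, rng):
        shape = (12, 10, 8)
        vol = Volume(rng.normal(size=shape), _grid(shape))
        back = mirror_volume(mirror_volume(vol))
        assert (back.data == vol.data).all()

    def test_centre_of_gravity_x_flips_sign(self, rng):
        shape = (12, 10, 8)
        affine = _grid(shape)
        data = rng.uniform(0.1, 1.0, size=shape)
        mask = Mask(np.ones(shape, bool), affine)
        s0 = striatal_summary(Volume(data, affine), mask)
        s1 = striatal_summary(mirror_volume(Volume(data, affine)), mask)
        assert s1.cog_mni[0] == pytest.approx(-s0.cog_mni[0], abs=1e-9)
        assert s1.cog_mni[1] == pytest.approx(s0.cog_mni[1], abs=1e-9)
        assert s1.cog_mni[2] == pytest.approx(s0.cog_mni[2], abs=1e-9)

    def test_asymmetric_grid_rejected(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = (-3.0, -9.0, -9.0)  # x planes at -3..15: not symmetric
        with pytest.raises(ValueError, match="symmetric"):
            mirror_volume(Volume(np.ones((10, 10, 10)), affine))


class TestStriatalSummary:
    def test_single_voxel(self):
        shape = (6, 6, 6)
        affine = _grid(shape)
        data = np.zeros(shape)
        data[2, 3, 4] = 1.7
        mask = np.zeros(shape, bool)
        mask[2, 3, 4] = True
        s = striatal_summary(Volume(data, affine), Mask(mask, affine))
        assert s.mean_local_sbr == pytest.approx(1.7)
        assert s.max_voxel_mni == pytest.approx(s.cog_mni)

    def test_two_voxel_midpoint(self):
        shape = (32, 8, 8)
        affine = _grid(shape, vox=2.0)
        data = np.zeros(shape)
        mask = np.zeros(shape, bool)
        for x in (-20.0, -30.0):
            ijk = tuple(np.round(spect.mni_to_voxel(affine, [x, 0.0, 0.0])).astype(int))
            data[ijk] = 3.0
            mask[ijk] = True
        s = striatal_summary(Volume(data, affine), Mask(mask, affine))
        assert s.cog_mni[0] == pytest.approx(-25.0)

    def test_matches_brute_force_oracle(self, rng):
        shape = (7, 6, 5)
        affine = _grid(shape)
        data = rng.uniform(0.1, 3.0, size=shape)
        mask = rng.random(shape) < 0.4
        s = striatal_summary(Volume(data, affine), Mask(mask, affine))
        vals, coords = [], []
        best, best_idx = -np.inf, None
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    if mask[i, j, k]:
                        vals.append(data[i, j, k])
                        coords.append(voxel_to_mni(affine, np.array([i, j, k])))
                        if data[i, j, k] > best:
                            best, best_idx = data[i, j, k], (i, j, k)
        vals = np.array(vals)
        coords = np.array(coords)
        assert s.mean_local_sbr == pytest.approx(vals.mean(), rel=1e-12)
        assert s.max_local_sbr == pytest.approx(vals.max(), rel=1e-12)
        assert s.max_local_sbr >= s.mean_local_sbr
        np.testing.assert_allclose(
            s.cog_mni, (coords * vals[:, None]).sum(0) / vals.sum(), rtol=1e-10
        )
        np.testing.assert_allclose(
            s.max_voxel_mni, voxel_to_mni(affine, np.array(best_idx)), rtol=1e-10
        )

    def test_empty_mask_rejected(self):
        shape = (4, 4, 4)
        affine = _grid(shape)
        with pytest.raises(ValueError, match="empty"):
            striatal_summary(
                Volume(np.ones(shape), affine), Mask(np.zeros(shape, bool), affine)
            )


class TestHemisphereAndOccipital:
    def test_restrict_left_keeps_negative_x_only(self):
        shape = (10, 6, 6)
        affine = _grid(shape)
        full = Mask(np.ones(shape, bool), affine)
        left = restrict_hemisphere(full, "left")
        idx = np.indices(shape).reshape(3, -1).T
        x = np.atleast_2d(voxel_to_mni(affine, idx.astype(float)))[:, 0].reshape(shape)
        np.testing.assert_array_equal(left.data, x < 0)

    def test_occipital_slab_is_posterior(self):
        occ = occipital_mask(synthetic.GRID_SHAPE, synthetic.GRID_AFFINE)
        idx = np.argwhere(occ.data).astype(float)
        y = np.atleast_2d(voxel_to_mni(synthetic.GRID_AFFINE, idx))[:, 1]
        assert occ.n_voxels > 0
        assert y.max() <= -44.0


class TestMedialShiftProperty:
    def test_max_voxel_moves_medially_with_depletion(self, small_cohort):
        """More depleted subjects peak at more medial (less negative x) voxels,
        the spatial signature of preferential lateral-putamen loss."""
        co = small_cohort
        rescaled = [spect.rescale_local_sbr(v, co.occipital) for v in co.volumes]
        mirrored = [
            spect.mirror_volume(v) if h == "left" else v
            for v, h in zip(rescaled, co.hands)
        ]
        mask = restrict_hemisphere(
            build_datstriatum_mask(mirrored, 2.0), "left"
        )
        summaries = [striatal_summary(v, mask) for v in mirrored]
        xs = [s.max_voxel_mni[0] for s in summaries]
        cogs = [s.cog_mni[0] for s in summaries]
        assert sps.spearmanr(co.global_deficit, xs).statistic > 0.25
        assert sps.spearmanr(co.global_deficit, cogs).statistic > 0.8
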