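"""Resting-state preprocessing and seed-based group connectivity."""

import numpy as np
import pytest

from datlearn import synthetic
from datlearn.connectivity import (
    BoldRun,
    average_maps,
    bandpass,
    framewise_displacement,
    group_connectivity,
    nuisance_regress,
    overlap_map,
    scrub,
    seed_map,
    smooth_volume,
)
from datlearn.spect import Mask, Volume
from datlearn.voxstats import SeedSpec


def _affine(vox=4.0, shape=(6, 6, 6)):
    a = np.diag([vox, vox, vox, 1.0])
    a[:3, 3] = -vox * (np.array(shape) - 1) / 2.0
    return a


def _run(data, tr=0.72, motion=None):
    shape = data.shape[:3]
    return BoldRun(data=data, affine=_affine(shape=shape), tr=tr, motion=motion)


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        fd = framewise_displacement(np.zeros((50, 6)))
        assert (fd == 0).all()

    def test_translation_jump_equals_magnitude(self):
        motion = np.zeros((20, 6))
        motion[10:, 0] = 0.6
        fd = framewise_displacement(motion)
        assert fd[10] == pytest.approx(0.6)
        assert fd[11] == 0.0

    def test_rotation_converts_on_50mm_sphere(self):
        motion = np.zeros((10, 6))
        motion[5:, 3] = 0.01
        fd = framewise_displacement(motion)
        assert fd[5] == pytest.approx(0.5)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="6"):
            framewise_displacement(np.zeros((10, 5)))

    def test_scrub_drops_spiked_frame(self, rng):
        data = rng.normal(size=(4, 4, 4, 30))
        motion = np.zeros((30, 6))
        motion[12:, 0] = 0.6
        run = scrub(_run(data, motion=motion), fd_max=0.5)
        assert not run.frame_keep[12]
        assert run.frame_keep.sum() == 29


class TestNuisanceRegress:
    def _masks(self, shape):
        wm = np.zeros(shape, bool)
        wm[0] = True
        csf = np.zeros(shape, bool)
        csf[-1] = True
        aff = _affine(shape=shape)
        return Mask(wm, aff), Mask(csf, aff)

    def test_global_signal_voxel_becomes_zero(self, rng):
        shape = (4, 4, 4)
        T = 60
        data = rng.normal(size=(*shape, T))
        # plant one voxel that exactly tracks the global mean signal;
        # planting changes the global mean, so solve g = (rest + g/N) -> g
        N = np.prod(shape)
        rest = data.reshape(-1, T).sum(axis=0) - data[1, 1, 1]
        data[1, 1, 1] = rest / (N - 1)  # then global mean == this voxel
        wm, csf = self._masks(shape)
        out = nuisance_regress(_run(data, motion=np.zeros((T, 6))), wm, csf)
        assert np.abs(out.data[1, 1, 1]).max() < 1e-8

    def test_residuals_orthogonal_to_confounds(self, rng):
        shape = (5, 5, 4)
        T = 80
        data = rng.normal(size=(*shape, T))
        motion = rng.normal(scale=0.01, size=(T, 6))
        wm, csf = self._masks(shape)
        run = _run(data, motion=motion)
        out = nuisance_regress(run, wm, csf)
        confounds = [np.ones(T), *motion.T,
                     data[wm.data].mean(0), data[csf.data].mean(0),
                     data.reshape(-1, T).mean(0)]
        resid = out.data.reshape(-1, T)
        for c in confounds:
            assert np.abs(resid @ c).max() < 1e-6 * np.abs(resid).sum()

    def test_matches_projection_oracle(self, rng):
        shape = (4, 4, 4)
        T = 50
        data = rng.normal(size=(*shape, T))
        motion = rng.normal(scale=0.01, size=(T, 6))
        wm, csf = self._masks(shape)
        out = nuisance_regress(_run(data, motion=motion), wm, csf)
        X = np.column_stack([
            np.ones(T), motion,
            data[wm.data].mean(0), data[csf.data].mean(0),
            data.reshape(-1, T).mean(0),
        ])
        P = X @ np.linalg.pinv(X)
        for idx in [(0, 0, 1), (2, 3, 1), (3, 2, 2)]:
            y = data[idx]
            np.testing.assert_allclose(out.data[idx], y - P @ y, atol=1e-8)

    def test_rank_deficient_confounds_named(self, rng):
        shape = (4, 4, 4)
        T = 40
        data = rng.normal(size=(*shape, T))
        motion = rng.normal(scale=0.01, size=(T, 6))
        wm, _ = self._masks(shape)
        with pytest.raises(ValueError, match="csf_mean"):
            nuisance_regress(_run(data, motion=motion), wm, wm)  # duplicated mask

    def test_motionless_run_is_accepted(self, rng):
        # constant-zero motion columns are vacuous, not an error
        shape = (4, 4, 4)
        T = 40
        data = rng.normal(size=(*shape, T))
        wm, csf = self._masks(shape)
        out = nuisance_regress(_run(data, motion=np.zeros((T, 6))), wm, csf)
        assert out.data.shape == data.shape


class TestBandpass:
    def _sine_run(self, freq, T=200, tr=0.72):
        t = np.arange(T) * tr
        series = np.sin(2 * np.pi * freq * t)
        data = np.tile(series, (4, 4, 4, 1))
        return _run(data, tr=tr), series

    def test_constant_series_removed(self):
        run = _run(np.full((4, 4, 4, 100), 3.0))
        out = bandpass(run)
        assert np.abs(out.data).max() < 1e-6

    def test_passband_gain_near_unity(self):
        run, series = self._sine_run(0.04)
        out = bandpass(run)
        gain = out.data[2, 2, 2].std() / series.std()
        assert gain == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuation(self):
        run, series = self._sine_run(0.2)
        out = bandpass(run)
        gain = out.data[2, 2, 2].std() / series.std()
        assert gain <= 0.10

    def test_invalid_band_rejected(self):
        run = _run(np.zeros((4, 4, 4, 50)))
        with pytest.raises(ValueError, match="exceed"):
            bandpass(run, low=0.08, high=0.01)


class TestSmoothing:
    def test_matches_nilearn_gaussian(self, rng):
        nib = pytest.importorskip("nibabel")
        nilearn_image = pytest.importorskip("nilearn.image")
        shape = (10, 10, 10)
        aff = _affine(vox=2.0, shape=shape)
        data = rng.normal(size=shape)
        ours = smooth_volume(data, aff, fwhm=5.0)
        theirs = np.asanyarray(
            nilearn_image.smooth_img(nib.Nifti1Image(data, aff), fwhm=5.0).dataobj
        )
        # interior agreement (edge handling differs between implementations)
        np.testing.assert_allclose(ours[2:-2, 2:-2, 2:-2], theirs[2:-2, 2:-2, 2:-2],
                                   atol=5e-3)


class TestSeedMap:
    # 6^3 grid at 4 mm spacing centred on the origin: the nearest voxel
    # centres sit at (+-2, +-2, +-2), so a 4 mm seed holds those 8 voxels
    SEED = SeedSpec(center_mni=(0.0, 0.0, 0.0), radius=4.0)

    def _sphere(self, shape=(6, 6, 6)):
        from datlearn.voxstats import sphere_mask

        return sphere_mask(self.SEED, shape, _affine(shape=shape)).data

    def test_self_correlation_clamped_finite(self, rng):
        shape = (6, 6, 6)
        T = 120
        data = rng.normal(size=(*shape, T))
        data[self._sphere()] = rng.normal(size=T)  # whole sphere = one series
        m = seed_map(_run(data), self.SEED, fwhm=0.0)
        assert np.isfinite(m.z_map.data).all()
        sphere_voxel = tuple(np.argwhere(self._sphere())[0])
        assert m.z_map.data[sphere_voxel] > 10.0  # r = 1 clamped before atanh

    def test_fisher_antisymmetry_under_negation(self, rng):
        shape = (6, 6, 6)
        T = 120
        data = rng.normal(size=(*shape, T))
        m = seed_map(_run(data), self.SEED, fwhm=0.0)
        neg = -data
        neg[self._sphere()] = data[self._sphere()]  # seed series unchanged
        m2 = seed_map(_run(neg), self.SEED, fwhm=0.0)
        far = (0, 0, 0)
        assert m2.z_map.data[far] == pytest.approx(-m.z_map.data[far], rel=1e-10)

    def test_attenuation_matches_closed_form(self, rng):
        # target = seed + noise(sd sigma) -> r = 1/sqrt(1 + sigma^2)
        shape = (6, 6, 6)
        T = 4000
        sigma = 1.5
        latent = rng.normal(size=T)
        data = rng.normal(scale=sigma, size=(*shape, T))
        data[0, 0, 0] += latent
        data[self._sphere()] = latent  # noiseless seed series
        m = seed_map(_run(data), self.SEED, fwhm=0.0)
        expected = 1.0 / np.sqrt(1.0 + sigma**2)
        assert np.tanh(m.z_map.data[0, 0, 0]) == pytest.approx(expected, abs=0.04)

    def test_zero_variance_seed_rejected(self, rng):
        shape = (6, 6, 6)
        data = rng.normal(size=(*shape, 50))
        data[self._sphere()] = 0.0
        with pytest.raises(ValueError, match="variance"):
            seed_map(_run(data), self.SEED, fwhm=0.0)


class TestGroupInference:
    def test_average_maps_idempotent_and_commutative(self, rng):
        shape = (5, 5, 5)
        aff = _affine(shape=shape)
        seed = SeedSpec((0.0, 0.0, 0.0), 5.0)
        from datlearn.connectivity import ConnectivityMap

        a = ConnectivityMap(Volume(rng.normal(size=shape), aff), "s", seed)
        b = ConnectivityMap(Volume(rng.normal(size=shape), aff), "s", seed)
        ab = average_maps([a, b]).z_map.data
        ba = average_maps([b, a]).z_map.data
        np.testing.assert_array_equal(ab, ba)
        np.testing.assert_array_equal(average_maps([a, a]).z_map.data, a.z_map.data)

    def test_identical_positive_blob_hits_p_floor(self, rng):
        shape = (6, 6, 6)
        aff = _affine(shape=shape)
        seed = SeedSpec((0.0, 0.0, 0.0), 5.0)
        from datlearn.connectivity import ConnectivityMap

        z = np.zeros(shape)
        z[2:4, 2:4, 2:4] = 1.0
        maps = [
            ConnectivityMap(Volume(z + rng.normal(scale=1e-3, size=shape), aff), f"s{i}", seed)
            for i in range(10)
        ]
        cs = group_connectivity(maps, n_perm=200, seed=4)
        assert cs.significant()
        assert cs.significant()[0].p_fwe == pytest.approx(1.0 / 201.0)

    def test_single_subject_rejected(self, rng):
        shape = (5, 5, 5)
        aff = _affine(shape=shape)
        from datlearn.connectivity import ConnectivityMap

        m = ConnectivityMap(Volume(rng.normal(size=shape), aff), "s", SeedSpec((0, 0, 0), 5.0))
        with pytest.raises(ValueError, match="3 subjects"):
            group_connectivity([m], n_perm=200, seed=1)


class TestOverlap:
    def _cluster_set(self, blob, rng):
        shape = blob.shape
        aff = _affine(shape=shape)
        seed = SeedSpec((0.0, 0.0, 0.0), 5.0)
        from datlearn.connectivity import ConnectivityMap

        maps = [
            ConnectivityMap(
                Volume(blob * 1.0 + rng.normal(scale=1e-3, size=shape), aff), f"s{i}", seed
            )
            for i in range(8)
        ]
        return group_connectivity(maps, n_perm=150, seed=2)

    def test_disjoint_and_identical_and_partial(self, rng):
        shape = (8, 8, 8)
        a = np.zeros(shape, bool)
        a[1:4, 1:4, 1:4] = True
        b = np.zeros(shape, bool)
        b[5:8, 5:8, 5:8] = True
        c = np.zeros(shape, bool)
        c[2:6, 1:4, 1:4] = True  # overlaps a in 2x3x3 = 18 voxels
        cs_a = self._cluster_set(a, rng)
        cs_b = self._cluster_set(b, rng)
        cs_c = self._cluster_set(c, rng)
        assert overlap_map(cs_a, cs_b).n_voxels == 0
        assert overlap_map(cs_a, cs_a).n_voxels == cs_a.significance_mask().n_voxels
        assert overlap_map(cs_a, cs_c).n_voxels == 18


class TestPlantedRecoveryPipeline:
    def test_preprocessing_order_and_recovery(self):
        """scrub -> nuisance -> band-pass -> seed map -> group inference
        recovers the planted seed-correlated support."""
        geo = synthetic.default_rsfmri_geometry()
        rng = np.random.default_rng(99)
        maps = []
        for i in range(12):
            run = synthetic.gen_rsfmri(
                n_frames=240, geometry=geo, seed=rng, motion_spikes=[(30, 0.7)]
            )
            pre = scrub(run, fd_max=0.5)
            assert not pre.frame_keep[30]
            pre = nuisance_regress(pre, geo.wm_mask, geo.csf_mask)
            pre = bandpass(pre)
            maps.append(seed_map(pre, geo.seed_spec, subject_id=f"r{i}", fwhm=5.0))
        cs = group_connectivity(maps, n_perm=300, seed=11)
        sig = cs.significance_mask().data
        truth = geo.target_mask.data | geo.seed_region.data
        dice = 2 * (sig & truth).sum() / (sig.sum() + truth.sum())
        assert dice >= 0.5
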