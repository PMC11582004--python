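"""Seed-based resting-state functional connectivity on normative BOLD data.

Per-run preprocessing follows the fixed order: motion scrubbing (frames
with framewise displacement > 0.5 mm are dropped), nuisance regression
(six motion parameters, mean white-matter, CSF and global signals plus an
intercept), and 0.01-0.08 Hz band-pass filtering of the residuals.  The
seed time series is extracted from the *unsmoothed* residual data inside a
5 mm sphere, target series are smoothed with a 5 mm FWHM Gaussian, and the
connectivity map is the Fisher z-transform of the seed-to-voxel Pearson
correlation.  Group inference is a voxelwise one-sample t-test on the z
maps with sign-flipping permutations providing the max-cluster-extent null,
mirroring the covariate-permutation scheme of the voxelwise SBR analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, signal, stats

from .spect import Mask, Volume
from .voxstats import (
    Cluster,
    ClusterSet,
    GlmResult,
    SeedSpec,
    T_SENTINEL,
    _label_clusters,
    _max_extents_from_t,
    cluster_threshold,
    sphere_mask,
)

__all__ = [
    "FD_ROTATION_RADIUS_MM",
    "Z_CLAMP",
    "BoldRun",
    "ConnectivityMap",
    "framewise_displacement",
    "scrub",
    "nuisance_regress",
    "bandpass",
    "smooth_volume",
    "seed_map",
    "average_maps",
    "group_connectivity",
    "overlap_map",
]

#: sphere radius converting head rotations (rad) to displacement (mm)
FD_ROTATION_RADIUS_MM = 50.0

#: correlations are clamped to |r| <= 1 - Z_CLAMP before the atanh transform
Z_CLAMP = 1e-12


@dataclass(frozen=True)
class BoldRun:
    """4-D BOLD series with per-frame motion parameters.

    ``motion`` columns are three translations (mm) then three rotations
    (rad); ``frame_keep`` marks frames that survive motion scrubbing.
    """

    data: np.ndarray  # (x, y, z, t)
    affine: np.ndarray
    tr: float = 0.72
    motion: np.ndarray | None = None
    frame_keep: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4 or data.shape[3] < 2:
            raise ValueError(f"BOLD data must be 4-D with >= 2 frames, got {data.shape}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.motion is not None:
            motion = np.asarray(self.motion, dtype=float)
            if motion.shape != (data.shape[3], 6):
                raise ValueError(
                    f"motion must be (n_frames, 6) = ({data.shape[3]}, 6), "
                    f"got {motion.shape}"
                )
            object.__setattr__(self, "motion", motion)
        keep = self.frame_keep
        if keep is None:
            keep = np.ones(data.shape[3], dtype=bool)
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (data.shape[3],):
            raise ValueError("frame_keep length must equal the frame count")
        object.__setattr__(self, "frame_keep", keep)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class ConnectivityMap:
    """Fisher-z seed-to-voxel correlation map for one subject/run."""

    z_map: Volume
    subject_id: str
    seed: SeedSpec


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Power-style framewise displacement in mm.

    FD(t) = sum of absolute backward differences of the three translations
    plus the three rotations converted to arc length on a 50 mm sphere;
    FD of the first frame is 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (n_frames, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub(run: BoldRun, fd_max: float = 0.5) -> BoldRun:
    """Flag frames whose framewise displacement exceeds ``fd_max`` mm."""
    if run.motion is None:
        raise ValueError("run carries no motion parameters to scrub on")
    fd = framewise_displacement(run.motion)
    return replace(run, frame_keep=fd <= fd_max)


def nuisance_regress(
    run: BoldRun,
    wm_mask: Mask,
    csf_mask: Mask,
    use_gsr: bool = True,
) -> BoldRun:
    """Regress nuisance signals out of every voxel time series.

    Confounds: intercept, the six motion parameters, mean white-matter and
    CSF signals and (optionally) the global mean signal.  Only kept frames
    enter the fit; the returned run contains the residual series of the
    kept frames treated as contiguous.  Residuals are orthogonal to every
    confound column.
    """
    if run.motion is None:
        raise ValueError("run carries no motion parameters")
    keep = run.frame_keep
    data = run.data[..., keep]
    motion = run.motion[keep]
    n = data.shape[3]

    names = ["intercept"] + [f"motion_{i}" for i in range(1, 7)]
    cols = [np.ones(n)] + [motion[:, i] for i in range(6)]
    flat = data.reshape(-1, n)
    for name, m in (("wm_mean", wm_mask), ("csf_mean", csf_mask)):
        if m.data.shape != run.data.shape[:3]:
            raise ValueError(f"{name} mask geometry does not match the run")
        cols.append(data[m.data].mean(axis=0))
        names.append(name)
    if use_gsr:
        cols.append(flat.mean(axis=0))
        names.append("global_mean")
    # constant-zero confounds (e.g. a motionless run) carry no variance to
    # remove; drop them rather than fail the rank check
    keep_cols = [0] + [
        j for j in range(1, len(cols)) if np.ptp(cols[j]) > 0
    ]
    cols = [cols[j] for j in keep_cols]
    names = [names[j] for j in keep_cols]
    X = np.column_stack(cols)
    if n < X.shape[1] + 2:
        raise ValueError(
            f"only {n} kept frames for {X.shape[1]} regressors; need at least "
            f"{X.shape[1] + 2}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column whose removal restores full rank
        for j in range(X.shape[1] - 1, 0, -1):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"confound matrix is rank deficient: column {names[j]!r}")
        raise ValueError("confound matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    resid = (flat.T - X @ beta).T.reshape(*run.data.shape[:3], n)
    return BoldRun(
        data=resid,
        affine=run.affine,
        tr=run.tr,
        motion=motion,
        frame_keep=np.ones(n, dtype=bool),
    )


def bandpass(run: BoldRun, low: float = 0.01, high: float = 0.08, order: int = 4) -> BoldRun:
    """Zero-phase Butterworth band-pass along the time axis.

    Applied forward-backward (no phase shift).  The censored series is
    treated as contiguous at the run's nominal TR.
    """
    if high <= low:
        raise ValueError(f"high cut-off must exceed low, got {low}..{high}")
    fs = 1.0 / run.tr
    if high >= fs / 2:
        raise ValueError(f"high cut-off {high} Hz is at/above Nyquist ({fs / 2:.3f} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # mirror padding the full series length tames the start-up transient of
    # the long-period low cut-off on short runs
    filtered = signal.sosfiltfilt(
        sos, run.data, axis=3, padtype="even", padlen=run.n_frames - 1
    )
    return replace(run, data=np.ascontiguousarray(filtered))


def _fwhm_to_sigma_vox(affine: np.ndarray, fwhm: float) -> np.ndarray:
    voxsizes = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    return (fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / voxsizes


def smooth_volume(data: np.ndarray, affine: np.ndarray, fwhm: float) -> np.ndarray:
    """Separable Gaussian smoothing with FWHM given in mm.

    Accepts a 3-D volume or a 4-D series (smoothed frame by frame).
    """
    if fwhm <= 0:
        return np.asarray(data, dtype=float)
    sigma = list(_fwhm_to_sigma_vox(affine, fwhm))
    if data.ndim == 4:
        sigma = sigma + [0.0]
    elif data.ndim != 3:
        raise ValueError(f"expected 3-D or 4-D data, got ndim={data.ndim}")
    return ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma=sigma)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1.0 + Z_CLAMP, 1.0 - Z_CLAMP))


def seed_map(
    run: BoldRun,
    seed: SeedSpec,
    subject_id: str = "",
    fwhm: float = 5.0,
) -> ConnectivityMap:
    """Seed-to-voxel correlation map of a preprocessed run.

    The seed series is the mean unsmoothed residual series over the seed
    sphere; target voxel series are smoothed before correlation.  The map
    stores Fisher-z values, with |r| clamped just below 1 so perfectly
    correlated voxels map to a large finite z rather than infinity.
    """
    keep = run.frame_keep
    if int(keep.sum()) < 10:
        raise ValueError(f"need >= 10 kept frames, got {int(keep.sum())}")
    sphere = sphere_mask(seed, run.data.shape[:3], run.affine)
    if sphere.n_voxels == 0:
        raise ValueError("seed sphere contains no voxel on this grid")
    data = run.data[..., keep]
    seed_series = data[sphere.data].mean(axis=0)
    s = seed_series - seed_series.mean()
    s_norm = float(np.sqrt(s @ s))
    if s_norm == 0:
        raise ValueError("seed time series has zero variance")
    smoothed = smooth_volume(data, run.affine, fwhm)
    flat = smoothed.reshape(-1, data.shape[3])
    yc = flat - flat.mean(axis=1, keepdims=True)
    y_norm = np.sqrt(np.einsum("vt,vt->v", yc, yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ s) / (y_norm * s_norm)
    r = np.where(y_norm > 0, r, 0.0)
    z = _fisher_z(r).reshape(run.data.shape[:3])
    return ConnectivityMap(
        z_map=Volume(z, run.affine), subject_id=subject_id, seed=seed
    )


def average_maps(maps: Sequence[ConnectivityMap]) -> ConnectivityMap:
    """Average z maps of the same subject (e.g. two phase-encoding runs)."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if not first.z_map.same_grid(m.z_map):
            raise ValueError("maps do not share a common grid")
    z = np.mean([m.z_map.data for m in maps], axis=0)
    return ConnectivityMap(
        z_map=Volume(z, first.z_map.affine),
        subject_id=first.subject_id,
        seed=first.seed,
    )


def _one_sample_t(M: np.ndarray, signs: np.ndarray | None = None) -> np.ndarray:
    """One-sample t over subjects (rows of M), optionally sign-flipped.

    ``signs`` is (B, n) of +-1; the per-voxel second moment is invariant
    under sign flips, so only the mean depends on the flip pattern.
    """
    n, V = M.shape
    ss = np.einsum("nv,nv->v", M, M)
    if signs is None:
        mu = M.mean(axis=0)[None, :]
    else:
        mu = (signs @ M) / n
    var = (ss[None, :] - n * mu**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mu / np.sqrt(var / n)
    t = np.where(np.isfinite(t), t, np.sign(mu) * T_SENTINEL)
    return np.clip(t, -T_SENTINEL, T_SENTINEL)


def group_connectivity(
    maps: Sequence[ConnectivityMap],
    mask: Mask | None = None,
    cdt_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int | None = None,
    direction: str = "positive",
) -> ClusterSet:
    """Group-level cluster inference on per-subject z maps.

    Voxelwise one-sample t-test (df = n - 1) against zero, clusters formed
    at the one-sided cluster-defining threshold, and cluster-extent FWE
    from a sign-flipping null (valid when the null distribution of z is
    symmetric about zero).
    """
    if len(maps) < 3:
        raise ValueError(f"need at least 3 subjects, got {len(maps)}")
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible permutation inference")
    first = maps[0].z_map
    for m in maps[1:]:
        if not first.same_grid(m.z_map):
            raise ValueError("maps do not share a common grid")
    if mask is None:
        mask = Mask(
            data=np.ones(first.shape, dtype=bool), affine=first.affine,
            provenance="whole grid",
        )
    n = len(maps)
    M = np.stack([m.z_map.data[mask.data] for m in maps])  # (n, V)
    df = n - 1
    t_obs = _one_sample_t(M)[0]

    t_grid = np.full(first.shape, np.nan)
    t_grid[mask.data] = t_obs
    mean_grid = np.full(first.shape, np.nan)
    mean_grid[mask.data] = M.mean(axis=0)
    glm = GlmResult(
        beta_map=Volume(mean_grid, first.affine),
        t_map=Volume(t_grid, first.affine),
        df=df,
        covariate_name="group_mean_z",
        direction=direction,
        mask=mask,
    )
    observed = cluster_threshold(glm, cdt_p, alpha)
    if not observed.clusters:
        return observed

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    sgn = 1.0 if direction == "positive" else -1.0
    T = sgn * _one_sample_t(M, signs)
    null_max = _max_extents_from_t(T, mask.data, observed.t_threshold)
    clusters = tuple(
        Cluster(
            voxels=c.voxels, extent=c.extent, peak_t=c.peak_t,
            peak_ijk=c.peak_ijk, peak_mni=c.peak_mni,
            p_fwe=float((1 + int((null_max >= c.extent).sum())) / (n_perm + 1)),
        )
        for c in observed.clusters
    )
    return ClusterSet(
        clusters=clusters, cdt_p=cdt_p, alpha=alpha,
        t_threshold=observed.t_threshold, df=df, direction=direction,
        shape=observed.shape, affine=observed.affine,
    )


def overlap_map(a: ClusterSet, b: ClusterSet) -> Mask:
    """Binary intersection of two cluster sets' significance masks."""
    if a.shape != b.shape or not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError("cluster sets do not share a common grid")
    ma = a.significance_mask()
    mb = b.significance_mask()
    return Mask(
        data=ma.data & mb.data, affine=a.affine,
        provenance="intersection of two significance masks",
    )
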