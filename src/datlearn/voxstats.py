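"""Mass-univariate voxelwise regression with cluster-level permutation FWE.

For every voxel inside a mask, the local SBR across subjects is regressed
on a behavioural covariate (design: intercept + covariate, df = n - 2).
Supra-threshold voxels at a one-sided cluster-defining threshold (default
uncorrected p < 0.001) are grouped into connected components under
18-connectivity (faces + edges).  Family-wise error across clusters is
controlled by permuting the covariate across subjects and recording the
maximum cluster extent of each permutation: the FWE-corrected p-value of an
observed cluster of extent k is ``(1 + #{permutation max extent >= k}) /
(n_perm + 1)``.  Peak voxels of significant clusters become the centres of
5 mm spherical seeds for the downstream connectivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .spect import Mask, Volume, voxel_to_mni

__all__ = [
    "T_SENTINEL",
    "GlmResult",
    "Cluster",
    "ClusterSet",
    "SeedSpec",
    "voxelwise_regression",
    "cluster_threshold",
    "permutation_fwe",
    "peak_seed",
    "sphere_mask",
    "cluster_table",
]

#: magnitude assigned to t statistics at numerically perfect (noise-free) fits
T_SENTINEL = 1e6

#: faces + edges neighbourhood used for cluster labelling
CONNECTIVITY_STRUCTURE = ndimage.generate_binary_structure(3, 2)


@dataclass(frozen=True)
class GlmResult:
    """Per-voxel slope and t maps for a single covariate."""

    beta_map: Volume
    t_map: Volume
    df: int
    covariate_name: str
    direction: str  # "positive" or "negative"
    mask: Mask


@dataclass(frozen=True)
class Cluster:
    voxels: np.ndarray  # (k, 3) voxel indices
    extent: int
    peak_t: float
    peak_ijk: tuple[int, int, int]
    peak_mni: tuple[float, float, float]
    p_fwe: float = float("nan")


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[Cluster, ...]
    cdt_p: float
    alpha: float
    t_threshold: float
    df: int
    direction: str
    shape: tuple[int, int, int]
    affine: np.ndarray

    def significant(self) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.p_fwe < self.alpha)

    def significance_mask(self) -> Mask:
        """Binary union of the significant clusters."""
        data = np.zeros(self.shape, dtype=bool)
        for c in self.significant():
            data[tuple(c.voxels.T)] = True
        return Mask(data=data, affine=self.affine,
                    provenance=f"clusters with p_fwe < {self.alpha}")


@dataclass(frozen=True)
class SeedSpec:
    """Sphere in MNI space used as a connectivity seed."""

    center_mni: tuple[float, float, float]
    radius: float = 5.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"seed radius must be > 0, got {self.radius}")


def _stack_masked(volumes: Sequence[Volume], mask: Mask) -> np.ndarray:
    first = volumes[0]
    for v in volumes:
        if not first.same_grid(v):
            raise ValueError("volumes do not share a common grid")
    if first.shape != mask.data.shape or not np.allclose(
        first.affine, mask.affine, atol=1e-6
    ):
        raise ValueError("mask geometry does not match the volumes")
    return np.stack([v.data[mask.data] for v in volumes])  # (n, V)


def _t_from_corr(r: np.ndarray, df: int) -> np.ndarray:
    """One-regressor OLS t statistic from the covariate-voxel correlation.

    |r| = 1 (noise-free voxel) maps to the documented sentinel magnitude.
    """
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    t = np.where(np.isfinite(t), t, np.sign(r) * T_SENTINEL)
    return np.clip(t, -T_SENTINEL, T_SENTINEL)


def voxelwise_regression(
    volumes: Sequence[Volume],
    covariate: Sequence[float],
    mask: Mask,
    direction: str = "positive",
    covariate_name: str = "covariate",
) -> GlmResult:
    """Per-voxel OLS of intensity on [intercept, covariate].

    Returns slope (beta) and t maps on the full grid with NaN outside the
    mask.  Voxels with zero variance inside the mask get beta = t = 0.
    """
    cov = np.asarray(covariate, dtype=float)
    n = len(volumes)
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if cov.shape != (n,):
        raise ValueError(f"covariate must have length {n}, got {cov.shape}")
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    c = cov - cov.mean()
    c_ss = float(c @ c)
    if c_ss <= 0:
        raise ValueError("covariate is constant: design matrix is rank deficient")
    Y = _stack_masked(volumes, mask)  # (n, V)
    Yc = Y - Y.mean(axis=0)
    y_ss = np.einsum("nv,nv->v", Yc, Yc)
    df = n - 2
    cy = c @ Yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = cy / c_ss
        r = cy / np.sqrt(c_ss * y_ss)
    zero_var = y_ss <= 0
    beta = np.where(zero_var, 0.0, beta)
    t = _t_from_corr(np.where(zero_var, 0.0, r), df)
    t = np.where(zero_var, 0.0, t)

    affine = volumes[0].affine
    beta_grid = np.full(mask.data.shape, np.nan)
    t_grid = np.full(mask.data.shape, np.nan)
    beta_grid[mask.data] = beta
    t_grid[mask.data] = t
    return GlmResult(
        beta_map=Volume(beta_grid, affine),
        t_map=Volume(t_grid, affine),
        df=df,
        covariate_name=covariate_name,
        direction=direction,
        mask=mask,
    )


def _label_clusters(
    supra: np.ndarray,
) -> list[np.ndarray]:
    """Connected components (18-connectivity) of a boolean grid."""
    labels, n = ndimage.label(supra, structure=CONNECTIVITY_STRUCTURE)
    return [np.argwhere(labels == i + 1) for i in range(n)]


def cluster_threshold(glm: GlmResult, cdt_p: float = 0.001, alpha: float = 0.05) -> ClusterSet:
    """Form clusters at a one-sided cluster-defining threshold.

    Supra-threshold voxels are those whose t statistic exceeds the one-sided
    critical value in the requested direction; an empty cluster set is a
    legitimate outcome.  Cluster p_fwe values are NaN until permutation
    inference assigns them.
    """
    if glm.df < 1:
        raise ValueError("need df >= 1")
    t_thr = float(stats.t.isf(cdt_p, glm.df))
    t = glm.t_map.data
    signed = t if glm.direction == "positive" else -t
    supra = np.nan_to_num(signed, nan=-np.inf) > t_thr
    clusters = []
    for vox in _label_clusters(supra):
        tvals = signed[tuple(vox.T)]
        peak_local = int(np.argmax(tvals))
        peak_ijk = tuple(int(i) for i in vox[peak_local])
        peak_mni = voxel_to_mni(glm.t_map.affine, np.array(peak_ijk))
        clusters.append(
            Cluster(
                voxels=vox,
                extent=len(vox),
                peak_t=float(t[peak_ijk]),
                peak_ijk=peak_ijk,
                peak_mni=tuple(float(x) for x in np.atleast_1d(peak_mni)[:3]),
            )
        )
    clusters.sort(key=lambda c: -c.extent)
    return ClusterSet(
        clusters=tuple(clusters),
        cdt_p=cdt_p,
        alpha=alpha,
        t_threshold=t_thr,
        df=glm.df,
        direction=glm.direction,
        shape=glm.t_map.shape,
        affine=glm.t_map.affine,
    )


def _max_extents_from_t(
    t_bv: np.ndarray, mask_data: np.ndarray, t_thr: float
) -> np.ndarray:
    """Maximum cluster extent per row of a (B, V) t matrix."""
    B = t_bv.shape[0]
    out = np.zeros(B, dtype=int)
    grid = np.zeros(mask_data.shape, dtype=bool)
    idx = np.nonzero(mask_data)
    for b in range(B):
        grid[:] = False
        grid[idx] = t_bv[b] > t_thr
        if grid.any():
            labels, n = ndimage.label(grid, structure=CONNECTIVITY_STRUCTURE)
            out[b] = int(np.bincount(labels.ravel())[1:].max())
    return out


def permutation_fwe(
    volumes: Sequence[Volume],
    covariate: Sequence[float],
    mask: Mask,
    direction: str = "positive",
    cdt_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int | None = None,
    covariate_name: str = "covariate",
) -> ClusterSet:
    """Cluster-extent FWE by permutation of the covariate.

    The covariate is shuffled across subjects ``n_perm`` times (seeded);
    each permutation's maximum supra-threshold cluster extent forms the
    null.  The resulting p_fwe values are bounded below by 1/(n_perm + 1),
    and identical seeds give bit-identical cluster sets.
    """
    if n_perm < 100:
        raise ValueError(f"need n_perm >= 100, got {n_perm}")
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible permutation inference")
    glm = voxelwise_regression(volumes, covariate, mask, direction, covariate_name)
    observed = cluster_threshold(glm, cdt_p, alpha)
    if not observed.clusters:
        return observed

    cov = np.asarray(covariate, dtype=float)
    n = len(cov)
    c = cov - cov.mean()
    c_norm = np.sqrt(float(c @ c))
    Y = _stack_masked(volumes, mask)
    Yc = Y - Y.mean(axis=0)
    y_norm = np.sqrt(np.einsum("nv,nv->v", Yc, Yc))
    y_norm[y_norm == 0] = np.inf  # zero-variance voxels can never exceed threshold
    df = n - 2
    sign = 1.0 if direction == "positive" else -1.0

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    P = c[perms]  # (B, n) permuted centred covariates
    R = (P @ Yc) / (c_norm * y_norm)  # (B, V)
    T = sign * _t_from_corr(R, df)
    null_max = _max_extents_from_t(T, mask.data, observed.t_threshold)

    clusters = tuple(
        Cluster(
            voxels=cl.voxels,
            extent=cl.extent,
            peak_t=cl.peak_t,
            peak_ijk=cl.peak_ijk,
            peak_mni=cl.peak_mni,
            p_fwe=float((1 + int((null_max >= cl.extent).sum())) / (n_perm + 1)),
        )
        for cl in observed.clusters
    )
    return ClusterSet(
        clusters=clusters,
        cdt_p=cdt_p,
        alpha=alpha,
        t_threshold=observed.t_threshold,
        df=df,
        direction=direction,
        shape=observed.shape,
        affine=observed.affine,
    )


def peak_seed(clusters: ClusterSet, radius: float = 5.0) -> SeedSpec:
    """Seed sphere centred on the peak voxel of the most significant cluster.

    Ties in p_fwe are broken by extent, then by peak t.
    """
    sig = clusters.significant()
    if not sig:
        raise ValueError("no significant cluster to seed from")
    sign = 1.0 if clusters.direction == "positive" else -1.0
    best = min(sig, key=lambda c: (c.p_fwe, -c.extent, -sign * c.peak_t))
    return SeedSpec(center_mni=best.peak_mni, radius=radius)


def sphere_mask(
    seed: SeedSpec, shape: tuple[int, int, int], affine: np.ndarray
) -> Mask:
    """All voxels whose MNI centre lies within the seed radius."""
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    xyz = np.atleast_2d(voxel_to_mni(affine, idx))
    d2 = ((xyz - np.asarray(seed.center_mni)) ** 2).sum(axis=1)
    data = (d2 <= seed.radius**2).reshape(shape)
    return Mask(
        data=data, affine=affine,
        provenance=f"sphere r={seed.radius} mm at {seed.center_mni}",
    )


def cluster_table(clusters: ClusterSet) -> "pd.DataFrame":
    """Tidy per-cluster table (extent, peak t, peak MNI, p_fwe)."""
    import pandas as pd

    rows = [
        dict(
            extent=c.extent,
            peak_t=c.peak_t,
            peak_x=c.peak_mni[0],
            peak_y=c.peak_mni[1],
            peak_z=c.peak_mni[2],
            p_fwe=c.p_fwe,
            significant=c.p_fwe < clusters.alpha,
        )
        for c in clusters.clusters
    ]
    return pd.DataFrame(
        rows,
        columns=["extent", "peak_t", "peak_x", "peak_y", "peak_z", "p_fwe", "significant"],
    )
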