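# Methods

## Behavioural model

Task performance in each 60-press block is summarised by the correct
sequence duration (CSD, seconds from the first to the last press of a
matched 4-1-3-2-4 span, i.e. four inter-press intervals), accuracy
(ACC = matched sequences / 12) and the performance index
PI = 100·exp(−CSD)·exp(ACC−1). The accuracy term of the index admits a
second algebraic reading, 100·exp(−CSD)·(exp(ACC)−1); both are
implemented (`pi_variant = "shifted_exp" | "expm1"`), and the shifted
exponential is the default because it yields a natural (0, 100] scale
with its supremum at perfect speed and accuracy and matches typical group
means of 10–20 observed with this family of finger-tapping indices.

Sequence matching is greedy, left-to-right and exact: an erroneous press
can neither anchor nor continue a match, and matches never overlap. For
the 4-1-3-2-4 template greedy matching is provably maximal because the
template cannot overlap itself; the test suite enforces equality with a
regex-based enumeration oracle on random key streams. Blocks with no
correct sequence have undefined CSD and PI (propagated as NaN, never
zero); the only imputation performed anywhere is the beginning-of-retest
rule, which fills exactly one missing value of the first two retest
blocks from the other one and flags the outcome.

## Local SBR and the striatal volume of interest

Volumes are assumed to be in MNI space on a shared grid; registration is
out of scope. The voxelwise specific binding ratio ("local SBR") divides
each voxel by the subject's mean over an occipital reference region, so
the reference mean is exactly 1 and the transform is invariant to global
scanner scaling (and hence idempotent). The packaged occipital region is
*parametric* — a posterior slab in MNI coordinates (y ≤ −44 mm, bounded
laterally and axially) rather than a traced anatomical atlas; the
rescaling step only requires a stable reference without specific
striatal uptake, and the synthetic phantoms carve the same region.

The striatal mask keeps voxels whose cohort-mean local SBR is ≥ 2.0
(inclusive at the boundary, chosen for determinism; the threshold is a
config value). The threshold is applied to the cohort mean only, not per
subject. Mirroring for left-hand trainers is a pure voxel-axis flip after
verifying that the grid is symmetric about x = 0 within half a voxel —
no interpolation, so mirroring twice is bit-exact. Analyses are then
restricted to the left hemisphere, where the task-relevant (contralateral)
striatum lies after mirroring. Arg-max ties in the per-subject summary are
broken by the smallest lexicographic voxel index, which matters only on
noise-free phantoms; centre-of-gravity weights exclude non-positive
intensities with a warning.

## Voxelwise inference

The per-voxel model is OLS on [intercept, covariate], df = n − 2,
implemented through the covariate–voxel correlation (algebraically
identical to the normal equations, validated against a closed-form oracle
at 1e−10). Noise-free voxels would give infinite t; these are clamped to
a documented sentinel magnitude of 1e6. Clusters are connected components
of supra-threshold voxels under 18-connectivity (faces + edges, a common
neuroimaging convention). Tests are one-sided per direction — positive
for online learning, negative for symptom severity — run as separate
contrasts.

Family-wise error across clusters is controlled by permutation rather
than random-field theory: the covariate rows are shuffled (seeded
generator, permutations drawn up front), each permutation's maximum
cluster extent forms the null, and
p_fwe = (1 + #{max extent ≥ observed}) / (n_perm + 1). This is exact at
small n, needs no smoothness estimation, and is fully testable: the
empirical family-wise error rate over 500 simulated null cohorts (16
subjects, spatially smoothed noise fields, independent covariate) falls
within the binomial band around 0.05. With spatially independent noise
the max-extent statistic is nearly degenerate (almost all clusters have
extent 1) and the test becomes conservative; smooth fields are the
realistic regime for SPECT data. Group connectivity inference reuses the
same machinery with a sign-flipping null (valid under a symmetric null
for the one-sample test on Fisher-z maps).

## Connectivity preprocessing

The per-run order is fixed: censor frames with framewise displacement
above 0.5 mm, regress nuisance signals, band-pass, then correlate. FD is
the Power convention — the sum of absolute backward differences of the
three translations plus the three rotations converted to arc length on a
50 mm sphere; the first frame has FD 0. Censoring drops frames before
regression and the censored series is treated as contiguous for
filtering; interpolation variants are out of scope. Confounds are an
intercept, the six motion parameters, mean white-matter and CSF signals
and the global mean; constant-zero confound columns (e.g. a motionless
synthetic run) are dropped as vacuous, while genuine collinearity is
rejected with the offending column named.

The band-pass is a 4th-order Butterworth applied forward–backward
(zero phase) with even (mirror) padding of the full series length — the
0.01 Hz edge has an impulse response of comparable length to a short run,
and mirror padding keeps the start-up transient from leaking stop-band
power (pass-band gain at 0.04 Hz is within 5% of unity, 0.2 Hz is
attenuated below 10% on a 200-frame run). Smoothing is a separable
Gaussian with σ = FWHM / (2√(2 ln 2)) per axis converted through the
voxel size; the seed series is always extracted from unsmoothed residuals
and targets from smoothed ones. Correlations are clamped to
|r| ≤ 1 − 1e−12 before the Fisher transform, so z is always finite. Two
runs of one subject are averaged at the z-map level.

## Synthetic study conditions

The generators produce every input kind at desk scale and define the
conditions under which the pipeline is validated.

*Striatal phantoms* live on a 4 mm MNI-like grid (24×28×20) with two
ellipsoidal striata (centres (±26, −2, 6) mm, semi-axes (10, 22, 12) mm),
an occipital slab at unit intensity, base SBR 3.0, voxel noise SD 0.08
and a random per-subject scanner scale. Dopamine-transporter loss has two
independent per-subject components, each uniform on [0.05, 0.95]: a
*global* deficit weighted anteriorly and laterally (maximal fractional
loss 0.35) and a *posterior* deficit confined to the posterior/lateral
putamen (also 0.35). The global component drives the upper-extremity
symptom score (12 points per unit deficit, noise SD 1.5, rounded and
clipped to 0–16); the posterior component sets the posterior-putamen
local SBR, which sets the online-learning target (3.5 PI units per unit
posterior SBR, noise SD 0.5). The independence of the two components is
what produces the planted spatial dissociation — a broad anterior-maximum
symptom cluster versus a small posterior learning cluster — and the
lateral weighting makes the surviving intensity peak drift medially with
severity. The ipsilateral striatum receives 70% of the contralateral
depletion, emulating early-stage asymmetry. Left-hand trainers (16/38 of
the cohort by default) get right-sided depletion and are flagged for
mirroring.

*Keystroke logs* draw inter-press intervals from a Gaussian around a mean
that decays exponentially (rate 0.35 per block) towards an asymptote; the
asymptote and starting points are inverted from the subject's target
end-of-training PI (13 ± 1), online-learning target, and offline loss
(−4 ± 1.5 PI). Wrong keys are injected per press (default probability
0.02). The realised online-learning measure correlates ≈ 0.9 with its
target; the residual realisation noise is part of the study conditions.

*Resting-state runs* share a band-limited unit-variance latent signal
between a seed sphere and a disjoint target blob; all other voxels are
white noise. The default SNR of 0.2 (noise SD 5 in latent units) was
chosen so that, after 0.01–0.08 Hz filtering concentrates the latent
signal, genuinely coupled voxels carry z ≈ 0.4–0.5 while the smoothing
halo around the blob stays below the group detection floor at n = 20 —
i.e. detection is specific to the planted support. Motion is a slow
random walk; planted spikes are steps in the x translation whose FD
equals the requested magnitude.

What the synthetic data do *not* emulate: SPECT point-spread and scatter,
anatomical variability between subjects (all phantoms share one grid and
geometry), BOLD haemodynamics, physiological noise spectra, and any
registration error. Passing recovery tests therefore demonstrates the
correctness and calibration of the statistics on data with the assumed
structure, not robustness to real-world preprocessing failures.

## Problem sizes and numerical choices

Validation runs use 40-subject cohorts with 5000 permutations for
recovery, 500 null cohorts × 300 permutations for error-rate calibration,
and 20 runs × 300 frames for connectivity — sizes chosen so the whole
validation completes in seconds on one core while keeping Monte-Carlo
error well below the decision margins. All permutation p-values have
floor 1/(n_perm + 1); all generators and permutation engines take
explicit seeds and are bit-reproducible. The Huynh–Feldt epsilon of the
mixed rmANOVA is the standard correction of the Greenhouse–Geisser
estimate computed from the pooled within-group covariance (the SPSS
convention; for a single group it equals the usual one-sample estimate),
capped at 1 and applied only when ε_GG < 1. Degenerate t-tests (zero
variance, equal means) return t = 0, p = 1 by convention.

## Known limitations

Full-scale voxelwise results from the original clinical imaging study are
not reproducible here because the underlying SPECT and fMRI volumes are
not public; the pipeline validates on the packaged per-participant
clinical table (which reproduces all cohort statistics exactly) and on
synthetic cohorts with planted effects. The rmANOVA F-statistics of the
behavioural sessions likewise require raw per-block data that only the
synthetic generator provides. The cluster-extent permutation test is
conservative on spatially independent noise; random-field and TFCE
alternatives are deliberately out of scope.
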