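"""Seeded generators for every input kind the pipeline consumes.

The cohort generator emulates the statistical structure the analysis
assumes, at desk scale (4 mm grids, small blobs):

* striatal "uptake" phantoms with two ellipsoidal striata, an occipital
  reference slab at unit intensity and an arbitrary per-subject global
  scanner scale.  Dopamine-transporter loss has two components per
  subject: a *global* deficit with an anterior emphasis (driving
  Parkinsonian motor symptoms, i.e. the upper-extremity sub-score UES) and
  a *posterior/lateral* deficit confined to the sensorimotor putamen
  (driving online motor-sequence learning).  This two-component structure
  reproduces the qualitative topology expected of the voxelwise analysis:
  a broad symptom-related cluster with an anterior maximum and a smaller
  learning-related cluster confined to the posterior putamen.
* keystroke logs with an exponential-approach-to-asymptote speed curve,
  random wrong-key errors and a retest session that starts below the
  end-of-training level (offline performance loss).
* 4-D resting-state series with a band-limited latent signal shared by a
  seed region and a planted target blob, white noise elsewhere, and
  optional motion spikes that trip the framewise-displacement threshold.

All generators are pure functions of their spec and seed: identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import (
    Block,
    ClinicalRecord,
    KeystrokeLog,
    RETEST_BLOCKS,
    SEQUENCE,
    TRAINING_BLOCKS,
)
from .connectivity import BoldRun
from .spect import Mask, Volume, occipital_mask, voxel_to_mni
from .voxstats import SeedSpec

__all__ = [
    "GRID_SHAPE",
    "GRID_AFFINE",
    "TABLE1_SHA256",
    "CohortSpec",
    "Cohort",
    "RsfmriGeometry",
    "gen_striatal_volume",
    "gen_keystroke_log",
    "gen_cohort",
    "gen_rsfmri",
    "default_rsfmri_geometry",
    "load_table1",
    "table1_frame",
]

# ---------------------------------------------------------------------------
# phantom geometry: a coarse 4 mm MNI-like grid, symmetric about x = 0
# ---------------------------------------------------------------------------

GRID_SHAPE: tuple[int, int, int] = (24, 28, 20)
GRID_AFFINE: np.ndarray = np.array(
    [
        [4.0, 0.0, 0.0, -46.0],
        [0.0, 4.0, 0.0, -64.0],
        [0.0, 0.0, 4.0, -36.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

_STRIATUM_CENTER = np.array([26.0, -2.0, 6.0])  # |x|, y, z in mm
_STRIATUM_SEMIAXES = np.array([10.0, 22.0, 12.0])

TABLE1_SHA256 = "5781e78a9182836893cbafb7afc8c0e3fed728243edf19bf8a7ecac828ba593f"


def _grid_mni(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return np.atleast_2d(voxel_to_mni(affine, idx)).reshape(*shape, 3)


def _striatum_mask(xyz: np.ndarray, side: str) -> np.ndarray:
    sign = -1.0 if side == "left" else 1.0
    center = _STRIATUM_CENTER * np.array([sign, 1.0, 1.0])
    d = (xyz - center) / _STRIATUM_SEMIAXES
    return (d**2).sum(axis=-1) <= 1.0


def _anterior_posterior_ramp(y: np.ndarray, y_ant: float = 10.0, y_post: float = -20.0) -> np.ndarray:
    """0 at/anterior of y_ant, 1 at/posterior of y_post."""
    return np.clip((y_ant - y) / (y_ant - y_post), 0.0, 1.0)


def _lateral_ramp(x: np.ndarray, x_med: float = 18.0, x_lat: float = 34.0) -> np.ndarray:
    return np.clip((np.abs(x) - x_med) / (x_lat - x_med), 0.0, 1.0)


def _global_field(xyz: np.ndarray) -> np.ndarray:
    """Global depletion weight: positive everywhere, anterior maximum,
    stronger laterally (so the surviving peak drifts medially)."""
    ap = 0.6 + 0.4 * (1.0 - _anterior_posterior_ramp(xyz[..., 1]))
    return ap * (0.6 + 0.4 * _lateral_ramp(xyz[..., 0]))


def _posterior_field(xyz: np.ndarray) -> np.ndarray:
    """Posterior/lateral depletion weight: zero in the anterior striatum."""
    a = _anterior_posterior_ramp(xyz[..., 1], y_ant=-4.0, y_post=-20.0)
    return a * (0.5 + 0.5 * _lateral_ramp(xyz[..., 0]))


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of the synthetic cohort.

    ``depletion_gradient`` is the maximal fractional SBR loss of the
    posterior/lateral component (at posterior deficit 1), and
    ``global_depletion`` the analogue for the global component.
    ``ues_effect`` is in UES points per unit global deficit and
    ``learning_effect`` in PI units per unit posterior local SBR.
    """

    n_subjects: int = 40
    seed: int = 0
    base_sbr: float = 3.0
    global_depletion: float = 0.35
    depletion_gradient: float = 0.35
    ues_effect: float = 12.0
    learning_effect: float = 3.5
    noise_sd_sbr: float = 0.08
    noise_sd_ues: float = 1.5
    noise_sd_online: float = 0.5
    error_rate: float = 0.02
    eot_pi: float = 13.0
    offline_drop: float = -4.0
    noise_sd_offline: float = 1.5
    left_hand_fraction: float = 16.0 / 38.0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        for name in ("noise_sd_sbr", "noise_sd_ues", "noise_sd_online", "noise_sd_offline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")


@dataclass(frozen=True)
class Cohort:
    """Everything the pipeline needs, plus the planted ground truth."""

    spec: CohortSpec
    records: tuple[ClinicalRecord, ...]
    hands: tuple[str, ...]
    volumes: tuple[Volume, ...]  # raw uptake, arbitrary per-subject scale
    training_logs: tuple[KeystrokeLog, ...]
    retest_logs: tuple[KeystrokeLog, ...]
    online_target: np.ndarray
    global_deficit: np.ndarray
    posterior_deficit: np.ndarray
    occipital: Mask
    striatum_truth: Mask  # left striatal ellipsoid (post-mirroring side)
    posterior_truth: Mask  # strongly learning-coupled posterior support


def gen_striatal_volume(
    spec: CohortSpec,
    deficit: float,
    posterior_deficit: float | None = None,
    rng: np.random.Generator | None = None,
    hand: str = "right",
    scale: float = 1.0,
) -> Volume:
    """One raw uptake phantom.

    The striatum contralateral to the task hand carries the full two-
    component depletion; the ipsilateral side gets a milder (70%) version,
    emulating the asymmetry of early Parkinsonian degeneration.  The
    occipital slab sits at unit intensity before the global ``scale``, so
    occipital rescaling recovers SBR units exactly.
    """
    if not 0.0 <= deficit <= 1.0:
        raise ValueError(f"deficit must lie in [0, 1], got {deficit}")
    if posterior_deficit is None:
        posterior_deficit = deficit
    if not 0.0 <= posterior_deficit <= 1.0:
        raise ValueError(f"posterior deficit must lie in [0, 1], got {posterior_deficit}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    xyz = _grid_mni(GRID_SHAPE, GRID_AFFINE)
    data = np.full(GRID_SHAPE, 0.2)
    occ = occipital_mask(GRID_SHAPE, GRID_AFFINE)
    data[occ.data] = 1.0

    contra = "left" if hand == "right" else "right"
    g_glob = _global_field(xyz)
    g_post = _posterior_field(xyz)
    for side, attenuation in ((contra, 1.0), ("right" if contra == "left" else "left", 0.7)):
        m = _striatum_mask(xyz, side)
        loss = attenuation * (
            spec.global_depletion * deficit * g_glob[m]
            + spec.depletion_gradient * posterior_deficit * g_post[m]
        )
        data[m] = spec.base_sbr * (1.0 - loss)
    if spec.noise_sd_sbr > 0:
        data = data + rng.normal(0.0, spec.noise_sd_sbr, size=GRID_SHAPE)
    data = np.clip(data, 0.01, None) * scale
    return Volume(data=data, affine=GRID_AFFINE.copy())


# ---------------------------------------------------------------------------
# keystroke simulator
# ---------------------------------------------------------------------------

def _expected_acc(error_rate: float) -> float:
    # probability that all five presses of a sequence are correct
    return (1.0 - error_rate) ** 5


def _ipi_for_pi(pi: float, error_rate: float) -> float:
    """Inter-press interval whose noise-free block PI equals ``pi``."""
    acc = _expected_acc(error_rate)
    ceiling = 100.0 * math.exp(acc - 1.0)
    if not 0.0 < pi < ceiling:
        raise ValueError(f"target PI {pi:.2f} outside the attainable (0, {ceiling:.2f})")
    csd = -math.log(pi / ceiling)
    return csd / 4.0


def _sample_block(
    index: int,
    mean_ipi: float,
    error_rate: float,
    rng: np.random.Generator,
    ipi_jitter: float = 0.08,
) -> Block:
    keys = np.tile(SEQUENCE, 12).astype(int)
    wrong = rng.random(60) < error_rate
    if wrong.any():
        offsets = rng.integers(1, 4, size=int(wrong.sum()))
        keys[wrong] = (keys[wrong] - 1 + offsets) % 4 + 1
    ipis = np.maximum(0.05, rng.normal(mean_ipi, ipi_jitter * mean_ipi, size=60))
    times = np.cumsum(ipis)
    presses = tuple(zip(times.tolist(), keys.tolist()))
    return Block(index=index, presses=presses)


def gen_keystroke_log(
    learning_rate: float,
    asymptote: float,
    error_rate: float,
    seed: int | np.random.Generator,
    initial_ipi: float | None = None,
    retest_initial_ipi: float | None = None,
    subject_id: str = "sim",
    hand: str = "right",
    ipi_jitter: float = 0.08,
) -> tuple[KeystrokeLog, KeystrokeLog]:
    """Simulate the full training (18 blocks) and retest (14 blocks) sessions.

    The mean inter-press interval decays exponentially from ``initial_ipi``
    towards ``asymptote`` at rate ``learning_rate`` per block; the retest
    restarts from ``retest_initial_ipi`` (slower than the end-of-training
    level when offline consolidation is incomplete) and re-approaches the
    same asymptote.  Wrong keys are injected per press with probability
    ``error_rate``.  Each block has exactly 60 presses.
    """
    if learning_rate <= 0 or asymptote <= 0:
        raise ValueError("learning_rate and asymptote must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if initial_ipi is None:
        initial_ipi = asymptote + 0.25
    if retest_initial_ipi is None:
        retest_initial_ipi = asymptote + 0.1

    def _session(session: str, n_blocks: int, start_ipi: float) -> KeystrokeLog:
        blocks = []
        for b in range(1, n_blocks + 1):
            mean_ipi = asymptote + (start_ipi - asymptote) * math.exp(
                -learning_rate * (b - 1)
            )
            blocks.append(_sample_block(b, mean_ipi, error_rate, rng, ipi_jitter))
        return KeystrokeLog(
            subject_id=subject_id, session=session, blocks=tuple(blocks), hand=hand
        )

    training = _session("training", TRAINING_BLOCKS, initial_ipi)
    retest = _session("retest", RETEST_BLOCKS, retest_initial_ipi)
    return training, retest


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full synthetic cohort.

    Per subject: a global deficit (uniform on [0.05, 0.95]) drives the UES
    (``ues_effect`` points per unit deficit, noisy, rounded and clipped to
    0-16) and an independent posterior deficit sets the posterior-putamen
    local SBR component, which in turn sets the online-learning target
    (``learning_effect`` PI units per unit posterior SBR).
    The keystroke simulator then realises that target through its speed
    curve.  Left-hand trainers (at the stated cohort proportion) receive
    right-sided depletion and are flagged for mirroring.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    # independent deficit components: the global one drives motor symptoms,
    # the posterior one drives learning, so the two voxelwise contrasts
    # pick out distinct (though spatially overlapping) striatal territories
    d_g = rng.uniform(0.05, 0.95, size=n)
    d_p = rng.uniform(0.05, 0.95, size=n)

    n_left = int(round(spec.left_hand_fraction * n))
    hands = np.array(["right"] * n)
    hands[rng.choice(n, size=n_left, replace=False)] = "left"

    xyz = _grid_mni(GRID_SHAPE, GRID_AFFINE)
    left_striatum = _striatum_mask(xyz, "left")
    g_post = _posterior_field(xyz)
    posterior_truth = left_striatum & (g_post >= 0.5)
    occ = occipital_mask(GRID_SHAPE, GRID_AFFINE)

    # posterior-specific local SBR component at the contralateral reference
    # (posterior field value 1); online learning is coupled to this
    # component only, mirroring the confinement of the learning
    # association to the posterior putamen
    posterior_sbr = spec.base_sbr * (1.0 - spec.depletion_gradient * d_p)
    online_target = spec.learning_effect * posterior_sbr + rng.normal(
        0.0, spec.noise_sd_online, size=n
    )
    offline_target = spec.offline_drop + rng.normal(0.0, spec.noise_sd_offline, size=n)
    ues = np.clip(
        np.rint(spec.ues_effect * d_g + rng.normal(0.0, spec.noise_sd_ues, size=n)),
        0,
        16,
    ).astype(int)

    volumes: list[Volume] = []
    records: list[ClinicalRecord] = []
    training_logs: list[KeystrokeLog] = []
    retest_logs: list[KeystrokeLog] = []
    caud_sel = {}
    for side in ("left", "right"):
        m = _striatum_mask(xyz, side)
        caud_sel[side] = (m & (xyz[..., 1] > 0), m & (xyz[..., 1] <= 0))

    for i in range(n):
        sid = f"sim{i + 1:03d}"
        hand = str(hands[i])
        scale = float(np.exp(rng.normal(np.log(40.0), 0.2)))
        vol = gen_striatal_volume(
            spec, float(d_g[i]), float(d_p[i]), rng=rng, hand=hand, scale=scale
        )
        volumes.append(vol)

        # BRASS-like regional SBR from the contralateral striatum
        contra = "left" if hand == "right" else "right"
        sbr_map = vol.data / vol.data[occ.data].mean()
        caud_m, put_m = caud_sel[contra]
        sbr_caud = float(sbr_map[caud_m].mean())
        sbr_put = float(sbr_map[put_m].mean())
        z_caud = (sbr_caud - spec.base_sbr) / 0.3
        z_put = (sbr_put - spec.base_sbr) / 0.3
        records.append(
            ClinicalRecord(
                subject_id=sid,
                age=float(np.round(rng.normal(64.0, 8.0))),
                sex="F" if rng.random() < 0.4 else "M",
                updrs_iii_total=int(np.clip(np.rint(ues[i] * 2.8 + rng.normal(2, 3)), 0, 80)),
                ues=int(ues[i]),
                sbr_caudate=round(sbr_caud, 3),
                sbr_putamen=round(sbr_put, 3),
                z_caudate=round(z_caud, 3),
                z_putamen=round(z_put, 3),
                ledd=0.0,
                diagnosis="PD" if z_put < -2.5 else "ET",
            )
        )

        eot_pi = float(np.clip(spec.eot_pi + rng.normal(0.0, 1.0), 2.0, 30.0))
        bot_pi = float(np.clip(eot_pi - online_target[i], 0.5, eot_pi - 0.2))
        bor_pi = float(np.clip(eot_pi + offline_target[i], 0.5, 30.0))
        asym = _ipi_for_pi(eot_pi, spec.error_rate)
        ipi_bot = _ipi_for_pi(bot_pi, spec.error_rate)
        ipi_bor = _ipi_for_pi(bor_pi, spec.error_rate)
        rate = 0.35
        f_mean = (1.0 + math.exp(-rate)) / 2.0  # mean decay factor, blocks 1-2
        initial = asym + (ipi_bot - asym) / f_mean
        retest_initial = asym + (ipi_bor - asym) / f_mean
        tr_log, rt_log = gen_keystroke_log(
            learning_rate=rate,
            asymptote=asym,
            error_rate=spec.error_rate,
            seed=rng,
            initial_ipi=max(0.06, initial),
            retest_initial_ipi=max(0.06, retest_initial),
            subject_id=sid,
            hand=hand,
        )
        training_logs.append(tr_log)
        retest_logs.append(rt_log)

    return Cohort(
        spec=spec,
        records=tuple(records),
        hands=tuple(str(h) for h in hands),
        volumes=tuple(volumes),
        training_logs=tuple(training_logs),
        retest_logs=tuple(retest_logs),
        online_target=online_target,
        global_deficit=d_g,
        posterior_deficit=d_p,
        occipital=occ,
        striatum_truth=Mask(left_striatum, GRID_AFFINE.copy(), "left striatal ellipsoid"),
        posterior_truth=Mask(
            posterior_truth, GRID_AFFINE.copy(), "posterior learning-coupled support"
        ),
    )


# ---------------------------------------------------------------------------
# resting-state generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RsfmriGeometry:
    shape: tuple[int, int, int]
    affine: np.ndarray
    seed_spec: SeedSpec
    seed_region: Mask
    target_mask: Mask
    wm_mask: Mask
    csf_mask: Mask


def default_rsfmri_geometry() -> RsfmriGeometry:
    """Small 4 mm grid with a seed sphere and a disjoint planted target blob."""
    shape = (12, 12, 10)
    affine = np.array(
        [
            [4.0, 0.0, 0.0, -22.0],
            [0.0, 4.0, 0.0, -22.0],
            [0.0, 0.0, 4.0, -18.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    xyz = _grid_mni(shape, affine)
    seed_spec = SeedSpec(center_mni=(-8.0, -8.0, 0.0), radius=5.0)
    seed_region = ((xyz - np.array(seed_spec.center_mni)) ** 2).sum(axis=-1) <= 5.0**2
    target = (
        (xyz[..., 0] >= 4) & (xyz[..., 0] <= 12)
        & (xyz[..., 1] >= 4) & (xyz[..., 1] <= 12)
        & (xyz[..., 2] >= -4) & (xyz[..., 2] <= 4)
    )
    wm = xyz[..., 0] <= -20.0
    csf = xyz[..., 0] >= 20.0
    return RsfmriGeometry(
        shape=shape,
        affine=affine,
        seed_spec=seed_spec,
        seed_region=Mask(seed_region, affine, "seed sphere"),
        target_mask=Mask(target, affine, "planted target blob"),
        wm_mask=Mask(wm, affine, "white-matter slab"),
        csf_mask=Mask(csf, affine, "CSF slab"),
    )


def _bandlimited_latent(
    n_frames: int, tr: float, rng: np.random.Generator,
    low: float = 0.01, high: float = 0.08,
) -> np.ndarray:
    pad = 200
    white = rng.normal(size=n_frames + 2 * pad)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    x = signal.sosfiltfilt(sos, white)[pad:-pad]
    return x / x.std()


def gen_rsfmri(
    n_frames: int = 400,
    tr: float = 0.72,
    geometry: RsfmriGeometry | None = None,
    snr: float = 0.2,
    motion_spikes: Sequence[tuple[int, float]] = (),
    seed: int | np.random.Generator = 0,
) -> BoldRun:
    """One synthetic resting-state run.

    Seed-region and target voxels share a band-limited latent signal of
    unit variance plus white noise of standard deviation ``1/snr``; all
    other voxels carry independent noise.  ``motion_spikes`` is a list of
    ``(frame, magnitude_mm)`` steps added to the x translation, producing
    a framewise displacement of exactly that magnitude at the given frame.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geo = geometry or default_rsfmri_geometry()
    latent = _bandlimited_latent(n_frames, tr, rng)
    noise_sd = 1.0 / snr
    data = rng.normal(0.0, noise_sd, size=(*geo.shape, n_frames))
    coupled = geo.seed_region.data | geo.target_mask.data
    data[coupled] += latent

    motion = np.cumsum(
        np.concatenate(
            [
                rng.normal(0.0, 0.005, size=(n_frames, 3)),
                rng.normal(0.0, 1e-4, size=(n_frames, 3)),
            ],
            axis=1,
        ),
        axis=0,
    )
    for frame, magnitude in motion_spikes:
        if not 1 <= frame < n_frames:
            raise ValueError(f"spike frame {frame} out of range [1, {n_frames})")
        motion[frame:, 0] += magnitude
    return BoldRun(data=data, affine=geo.affine, tr=tr, motion=motion)


# ---------------------------------------------------------------------------
# packaged clinical table
# ---------------------------------------------------------------------------

def table1_frame() -> pd.DataFrame:
    """The packaged 38-participant clinical table as a DataFrame."""
    ref = importlib.resources.files("datlearn") / "data" / "table1.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise ValueError(
            f"clinical table fixture is corrupt: sha256 {digest} != {TABLE1_SHA256}"
        )
    import io

    return pd.read_csv(io.BytesIO(raw))


def load_table1() -> list[ClinicalRecord]:
    """Load the packaged clinical table as typed records (checksum-verified)."""
    df = table1_frame()
    records = [
        ClinicalRecord(
            subject_id=str(row.subject_id),
            age=float(row.age),
            sex=str(row.sex),
            updrs_iii_total=int(row.updrs_iii_total),
            ues=int(row.ues),
            sbr_caudate=float(row.sbr_caudate),
            sbr_putamen=float(row.sbr_putamen),
            z_caudate=float(row.z_caudate),
            z_putamen=float(row.z_putamen),
            ledd=float(row.ledd),
            diagnosis=str(row.diagnosis),
        )
        for row in df.itertuples()
    ]
    if len(records) != 38:
        raise ValueError(f"expected 38 participants, got {len(records)}")
    return records
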