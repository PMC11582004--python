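"""Behavioural scoring of the sequential finger-tapping task.

Participants repeatedly tap a five-item finger sequence (little, index,
ring, middle, little finger -> keys 4-1-3-2-4); each practice block stops
after 60 button presses, so at most 12 correct sequences fit in a block.
From the keystroke stream each block yields

* ``CSD`` -- correct sequence duration: mean seconds to execute one correct
  sequence in the block (undefined when the block contains none);
* ``ACC`` -- number of correct sequences divided by the maximum of 12;
* ``PI``  -- a performance index combining both on a 0-100 scale,
  ``PI = 100 * exp(-CSD) * exp(ACC - 1)`` under the default parametrisation.

Session-level learning measures are computed from block-wise PI values:
beginning-of-training (BoT, mean PI of training blocks 1-2),
end-of-training (EoT, blocks 15-18) and beginning-of-retest (BoR, retest
blocks 1-2).  Online learning is ``EoT - BoT`` and offline consolidation is
``BoR - EoT``.  When exactly one of the two BoR blocks has an undefined PI
(no correct sequence produced), the missing value is imputed from the other
block and the outcome is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEQUENCE",
    "TRAINING_BLOCKS",
    "RETEST_BLOCKS",
    "MAX_SEQUENCES_PER_BLOCK",
    "PRESSES_PER_BLOCK",
    "PI_VARIANTS",
    "Block",
    "KeystrokeLog",
    "BlockScore",
    "SessionCurve",
    "LearningOutcome",
    "ClinicalRecord",
    "match_sequences",
    "score_block",
    "compute_pi",
    "score_session",
    "learning_metrics",
    "ues_score",
    "read_keystroke_csv",
    "write_keystroke_csv",
    "session_curves_frame",
    "learning_outcomes_frame",
]

#: the practised five-item finger sequence (1=index .. 4=little finger)
SEQUENCE: tuple[int, ...] = (4, 1, 3, 2, 4)

TRAINING_BLOCKS = 18
RETEST_BLOCKS = 14
PRESSES_PER_BLOCK = 60
MAX_SEQUENCES_PER_BLOCK = PRESSES_PER_BLOCK // len(SEQUENCE)  # 12

#: supported algebraic readings of the performance-index formula
PI_VARIANTS = ("shifted_exp", "expm1")

_VALID_KEYS = frozenset((1, 2, 3, 4))
_SESSIONS = ("training", "retest")


@dataclass(frozen=True)
class Block:
    """One practice block: ordered key presses with onsets in seconds."""

    index: int
    presses: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"block index must be >= 1, got {self.index}")
        times = [t for t, _ in self.presses]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"press times must be strictly increasing in block {self.index}"
            )
        bad = sorted({k for _, k in self.presses} - _VALID_KEYS)
        if bad:
            raise ValueError(
                f"invalid key value(s) {bad} in block {self.index}; keys must be 1-4"
            )

    @property
    def keys(self) -> tuple[int, ...]:
        return tuple(k for _, k in self.presses)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.presses)


@dataclass(frozen=True)
class KeystrokeLog:
    """Key presses of one subject in one session (training or retest)."""

    subject_id: str
    session: str
    blocks: tuple[Block, ...]
    hand: str = "right"

    def __post_init__(self) -> None:
        if self.session not in _SESSIONS:
            raise ValueError(f"session must be one of {_SESSIONS}, got {self.session!r}")
        if self.hand not in ("left", "right"):
            raise ValueError(f"hand must be 'left' or 'right', got {self.hand!r}")
        limit = TRAINING_BLOCKS if self.session == "training" else RETEST_BLOCKS
        if len(self.blocks) > limit:
            raise ValueError(
                f"{self.session} session allows at most {limit} blocks, got {len(self.blocks)}"
            )


@dataclass(frozen=True)
class BlockScore:
    """Per-block speed/accuracy summary.

    ``csd`` and ``pi`` are NaN when the block contains no correct sequence.
    """

    n_correct: int
    acc: float
    csd: float
    pi: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pi)


@dataclass(frozen=True)
class SessionCurve:
    subject_id: str
    session: str
    scores: tuple[BlockScore, ...]
    partial: bool = False

    @property
    def pi(self) -> np.ndarray:
        return np.array([s.pi for s in self.scores], dtype=float)


@dataclass(frozen=True)
class LearningOutcome:
    """BoT/EoT/BoR baselines and derived online/offline learning measures."""

    subject_id: str
    bot: float
    eot: float
    bor: float
    online: float
    offline: float
    imputed_bor: bool = False
    valid: bool = True


@dataclass(frozen=True)
class ClinicalRecord:
    """One row of the clinical/imaging table for a DaT-SPECT participant."""

    subject_id: str
    age: float
    sex: str
    updrs_iii_total: int
    ues: int
    sbr_caudate: float
    sbr_putamen: float
    z_caudate: float
    z_putamen: float
    ledd: float
    diagnosis: str

    def __post_init__(self) -> None:
        if not 0 <= self.ues <= 16:
            raise ValueError(f"UES must lie in [0, 16], got {self.ues}")
        if self.diagnosis not in ("PD", "ET", "RBD"):
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")


def match_sequences(
    block: Block | Sequence[tuple[float, int]],
    template: Sequence[int] = SEQUENCE,
) -> list[tuple[int, int, float]]:
    """Find correct sequences in a key stream.

    Greedy left-to-right exact matching of ``template`` against the block's
    key stream; matches never overlap, and an erroneous press simply cannot
    anchor or continue a match.  Returns ``(start, end, duration)`` tuples of
    press indices (inclusive) and the first-to-last press time span.
    """
    if isinstance(block, Block):
        presses = block.presses
    else:
        presses = tuple(block)
        bad = sorted({k for _, k in presses} - _VALID_KEYS)
        if bad:
            raise ValueError(f"invalid key value(s) {bad}; keys must be 1-4")
    if len(template) != 5:
        raise ValueError(f"template must have 5 items, got {len(template)}")
    keys = [k for _, k in presses]
    times = [t for t, _ in presses]
    tpl = tuple(template)
    m = len(tpl)
    out: list[tuple[int, int, float]] = []
    i = 0
    while i + m <= len(keys):
        if tuple(keys[i : i + m]) == tpl:
            out.append((i, i + m - 1, times[i + m - 1] - times[i]))
            i += m
        else:
            i += 1
    return out


def compute_pi(csd: float, acc: float, variant: str = "shifted_exp") -> float:
    """Performance index from correct-sequence duration and accuracy.

    Default reading: ``100 * exp(-csd) * exp(acc - 1)``, strictly in
    (0, 100] on the legal domain with its supremum at (csd -> 0, acc = 1).
    The ``expm1`` variant reads the accuracy term as ``exp(acc) - 1``
    instead; it is provided because the printed formula admits both
    groupings.  NaN inputs (undefined CSD) propagate to a NaN PI.
    """
    if variant not in PI_VARIANTS:
        raise ValueError(f"variant must be one of {PI_VARIANTS}, got {variant!r}")
    if math.isnan(csd):
        return math.nan
    if csd < 0:
        raise ValueError(f"csd must be >= 0, got {csd}")
    if not 0.0 <= acc <= 1.0:
        raise ValueError(f"acc must lie in [0, 1], got {acc}")
    if variant == "shifted_exp":
        return 100.0 * math.exp(-csd) * math.exp(acc - 1.0)
    return 100.0 * math.exp(-csd) * (math.exp(acc) - 1.0)


def score_block(
    matches: Sequence[tuple[int, int, float]],
    presses: Sequence[tuple[float, int]],
    pi_variant: str = "shifted_exp",
) -> BlockScore:
    """Summarise one block from its matched sequences.

    CSD is the mean duration of the matched spans and is NaN (undefined)
    for a block without any correct sequence; the PI inherits that NaN.
    """
    n = len(matches)
    if n > MAX_SEQUENCES_PER_BLOCK:
        raise ValueError(f"{n} matches exceed the {MAX_SEQUENCES_PER_BLOCK} maximum")
    acc = n / MAX_SEQUENCES_PER_BLOCK
    if n == 0:
        return BlockScore(n_correct=0, acc=0.0, csd=math.nan, pi=math.nan)
    csd = float(np.mean([d for _, _, d in matches]))
    return BlockScore(n_correct=n, acc=acc, csd=csd, pi=compute_pi(csd, acc, pi_variant))


def score_session(
    log: KeystrokeLog,
    template: Sequence[int] = SEQUENCE,
    pi_variant: str = "shifted_exp",
) -> SessionCurve:
    """Score every block of a session and return the PI learning curve."""
    expected = TRAINING_BLOCKS if log.session == "training" else RETEST_BLOCKS
    scores = tuple(
        score_block(match_sequences(b, template), b.presses, pi_variant)
        for b in log.blocks
    )
    return SessionCurve(
        subject_id=log.subject_id,
        session=log.session,
        scores=scores,
        partial=len(scores) != expected,
    )


def _mean_defined(values: Iterable[float]) -> float:
    vals = list(values)
    return float(np.mean(vals)) if vals else math.nan


def learning_metrics(training: SessionCurve, retest: SessionCurve) -> LearningOutcome:
    """Derive BoT/EoT/BoR and the online/offline learning measures.

    BoT = mean PI of training blocks 1-2, EoT = mean PI of training blocks
    15-18, BoR = mean PI of retest blocks 1-2.  If exactly one BoR block has
    an undefined PI it is imputed from the other; if both are undefined the
    outcome is flagged invalid.  Identities ``online = eot - bot`` and
    ``offline = bor - eot`` hold exactly.
    """
    if len(training.scores) != TRAINING_BLOCKS:
        raise ValueError(
            f"training session must have {TRAINING_BLOCKS} scored blocks, "
            f"got {len(training.scores)}"
        )
    if len(retest.scores) < 2:
        raise ValueError("retest session must have at least 2 scored blocks")
    pi_train = training.pi
    bot = float(np.mean(pi_train[:2]))
    eot = float(np.mean(pi_train[14:18]))
    b1, b2 = retest.pi[:2]
    imputed = False
    if math.isnan(b1) and math.isnan(b2):
        return LearningOutcome(
            subject_id=training.subject_id,
            bot=bot, eot=eot, bor=math.nan,
            online=eot - bot, offline=math.nan,
            imputed_bor=False, valid=False,
        )
    if math.isnan(b1) or math.isnan(b2):
        bor = b2 if math.isnan(b1) else b1
        imputed = True
    else:
        bor = (b1 + b2) / 2.0
    return LearningOutcome(
        subject_id=training.subject_id,
        bot=bot, eot=eot, bor=float(bor),
        online=eot - bot, offline=float(bor) - eot,
        imputed_bor=imputed, valid=True,
    )


def ues_score(
    rigidity: int,
    finger_tapping: int,
    hand_movements: int,
    pronation_supination: int,
) -> int:
    """Upper-extremity sub-score: sum of the four motor-exam items most
    relevant to task execution, each rated 0-4, giving a 0-16 range."""
    items = {
        "rigidity": rigidity,
        "finger_tapping": finger_tapping,
        "hand_movements": hand_movements,
        "pronation_supination": pronation_supination,
    }
    for name, v in items.items():
        if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
            raise ValueError(f"{name} must be an integer in [0, 4], got {v!r}")
    return int(sum(items.values()))


# ---------------------------------------------------------------------------
# keystroke-log dialect: long-format delimited text, one row per press
# ---------------------------------------------------------------------------

def write_keystroke_csv(logs: Iterable[KeystrokeLog], path: str | Path, sep: str = ",") -> None:
    rows = []
    for log in logs:
        for block in log.blocks:
            for t, key in block.presses:
                rows.append(
                    (log.subject_id, log.session, log.hand, block.index, t, key)
                )
    pd.DataFrame(
        rows, columns=["subject", "session", "hand", "block", "t", "key"]
    ).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_keystroke_csv(path: str | Path, sep: str = ",") -> list[KeystrokeLog]:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = {"subject", "session", "block", "t", "key"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"keystroke file {path} lacks column(s) {sorted(missing)}")
    if "hand" not in df.columns:
        df["hand"] = "right"
    logs = []
    for (subject, session, hand), g in df.groupby(
        ["subject", "session", "hand"], sort=True
    ):
        blocks = []
        for idx, bg in g.groupby("block", sort=True):
            bg = bg.sort_values("t")
            presses = tuple(zip(bg["t"].astype(float), bg["key"].astype(int)))
            blocks.append(Block(index=int(idx), presses=presses))
        logs.append(
            KeystrokeLog(
                subject_id=str(subject), session=str(session),
                blocks=tuple(blocks), hand=str(hand),
            )
        )
    return logs


def session_curves_frame(curves: Iterable[SessionCurve]) -> pd.DataFrame:
    """Tidy per-block table: one row per (subject, session, block)."""
    rows = []
    for c in curves:
        for i, s in enumerate(c.scores, start=1):
            rows.append(
                dict(subject=c.subject_id, session=c.session, block=i,
                     n_correct=s.n_correct, acc=s.acc, csd=s.csd, pi=s.pi)
            )
    return pd.DataFrame(rows)


def learning_outcomes_frame(outcomes: Iterable[LearningOutcome]) -> pd.DataFrame:
    rows = [
        dict(subject=o.subject_id, bot=o.bot, eot=o.eot, bor=o.bor,
             online=o.online, offline=o.offline,
             imputed_bor=o.imputed_bor, valid=o.valid)
        for o in outcomes
    ]
    return pd.DataFrame(rows)
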