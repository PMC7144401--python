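"""Objective sleepiness summaries of a staged recording.

Three parameters reduce a per-second vigilance stage sequence to the
quantities used in arousal-regulation research:

* stage-time proportions for the aggregated stages 0, A (A1+A2+A3),
  B (B1+B2/3) and C, over artifact-free seconds;
* the mean vigilance value (MVV), the average of the per-second stage
  scores (stage 0 = 7 ... stage C = 1), range 1-7;
* the arousal stability score (ASS), an 11-point ordinal summary of how
  far and how early arousal declined during the recording.

The ASS cascade (score 11 most stable, 1 least stable):

===== ==========================================================
score criterion
===== ==========================================================
11    only stages 0 and A1 occur (rigidity)
10    only stages 0 and A occur (rigidity)
9/8/7 >= 1/3 of seconds are B stages; first B in minute
      11-15 / 6-10 / 1-5
6/5/4 >= 1/3 of seconds are B2/3; first B2/3 in minute
      11-15 / 6-10 / 1-5
3/2/1 at least one C second; first C in minute 11-15 / 6-10 / 1-5
===== ==========================================================

Because any B2/3 second is also a B second, the criteria overlap; the
cascade applies them in order of increasing stability (C, then B2/3,
then B, then rigidity), so the least stable applicable level wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .staging import _STAGE_TO_CODE, Stage, StageSequence

__all__ = [
    "ArousalSummary",
    "stage_proportions",
    "mean_vigilance_value",
    "arousal_stability_score",
    "summarize_arousal",
]

_C0 = _STAGE_TO_CODE[Stage.STAGE_0]
_CA = (_STAGE_TO_CODE[Stage.A1], _STAGE_TO_CODE[Stage.A2], _STAGE_TO_CODE[Stage.A3])
_CB1 = _STAGE_TO_CODE[Stage.B1]
_CB23 = _STAGE_TO_CODE[Stage.B23]
_CC = _STAGE_TO_CODE[Stage.C]


@dataclass(frozen=True)
class ArousalSummary:
    """Objective sleepiness parameters of one subject."""

    prop_0: float
    prop_a: float
    prop_b: float
    prop_c: float
    mvv: float
    ass: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = self.prop_0 + self.prop_a + self.prop_b + self.prop_c
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage proportions sum to {total}, not 1")
        if not 1.0 <= self.mvv <= 7.0:
            raise ValueError("MVV outside [1, 7]")
        if self.ass not in range(1, 12):
            raise ValueError("ASS outside 1..11")


def _unmasked(sequence: StageSequence) -> np.ndarray:
    codes = sequence.unmasked_codes()
    if codes.size == 0:
        raise ValueError("sequence has no unmasked seconds")
    return codes


def stage_proportions(sequence: StageSequence) -> tuple[float, float, float, float]:
    """Proportions of unmasked time in stages 0, A, B and C (sum to 1)."""
    codes = _unmasked(sequence)
    n = codes.size
    p0 = np.sum(codes == _C0) / n
    pa = np.isin(codes, _CA).sum() / n
    pb = np.isin(codes, (_CB1, _CB23)).sum() / n
    pc = np.sum(codes == _CC) / n
    return float(p0), float(pa), float(pb), float(pc)


def mean_vigilance_value(sequence: StageSequence) -> float:
    """Arithmetic mean of per-second vigilance scores over unmasked
    seconds, range 1 (all C) to 7 (all stage 0).  Reported unrounded."""
    codes = _unmasked(sequence)
    score_table = np.array([7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
    return float(score_table[codes].mean())


def _first_emergence_bin(member: np.ndarray, bin_seconds: int) -> int:
    """0-based 5-minute bin (0: minutes 1-5, 1: 6-10, 2: 11+) of the first
    True second.  Bins count wall-clock seconds, masked ones included."""
    first_minute = int(np.flatnonzero(member)[0] // bin_seconds)  # 0-based
    return min(first_minute // 5, 2)


def arousal_stability_score(
    sequence: StageSequence,
    bin_seconds: int = 60,
    details: bool = False,
):
    """Arousal stability score (1-11) of a stage sequence.

    Minute bins are wall-clock (masked seconds keep their position);
    the one-third shares are computed over unmasked seconds only.  First
    emergence after minute 15 is mapped to the 11-15 bin.  Sequences
    shorter than 15 minutes are scored with the same rules and flagged.

    ``bin_seconds`` rescales the minute for reduced test fixtures.
    """
    codes = np.asarray(sequence.codes)
    unmasked = _unmasked(sequence)
    n = unmasked.size
    flags: list[str] = []
    if codes.size < 15 * bin_seconds:
        flags.append("short_recording")

    is_c = codes == _CC
    is_b23 = codes == _CB23
    is_b = (codes == _CB1) | is_b23

    if is_c.any():
        b = _first_emergence_bin(is_c, bin_seconds)
        score = (1, 2, 3)[b]
        if b == 2 and np.flatnonzero(is_c)[0] // bin_seconds >= 15:
            flags.append("late_emergence")
    elif np.sum(unmasked == _CB23) >= n / 3:
        b = _first_emergence_bin(is_b23, bin_seconds)
        score = (4, 5, 6)[b]
        if b == 2 and np.flatnonzero(is_b23)[0] // bin_seconds >= 15:
            flags.append("late_emergence")
    elif np.isin(unmasked, (_CB1, _CB23)).sum() >= n / 3:
        b = _first_emergence_bin(is_b, bin_seconds)
        score = (7, 8, 9)[b]
        if b == 2 and np.flatnonzero(is_b)[0] // bin_seconds >= 15:
            flags.append("late_emergence")
    else:
        only_0_a1 = np.isin(unmasked, (_C0, _STAGE_TO_CODE[Stage.A1])).all()
        only_0_a = np.isin(unmasked, (_C0,) + _CA).all()
        if only_0_a1:
            score = 11
        elif only_0_a:
            score = 10
        else:
            # B present but under one third: the share criterion governs
            score = 10
            flags.append("sub_threshold_b")
    if details:
        return score, tuple(flags)
    return score


def summarize_arousal(sequence: StageSequence) -> ArousalSummary:
    """All three objective parameters of one stage sequence."""
    p0, pa, pb, pc = stage_proportions(sequence)
    ass, flags = arousal_stability_score(sequence, details=True)
    return ArousalSummary(
        prop_0=p0,
        prop_a=pa,
        prop_b=pb,
        prop_c=pc,
        mvv=mean_vigilance_value(sequence),
        ass=ass,
        flags=flags,
    )
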