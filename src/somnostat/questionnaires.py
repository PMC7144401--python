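"""Scoring of the subjective sleepiness instruments and group assignment.

Instruments covered:

* ESS — Epworth Sleepiness Scale: 8 items, each 0-3; total 0-24; a total
  above 10 flags excessive daytime sleepiness (EDS).
* KSS — Karolinska Sleepiness Scale: single item, 1 (extremely alert) to
  10 (extremely sleepy); administered before and after the recording.
* SSS — Stanford Sleepiness Scale: single item, 1-7; pre and post.
* VAS — visual analogue sleepiness scale, 0 (not at all) to 100 (very
  much); pre and post.
* ASLEEP — self-assessed likelihood of having fallen asleep during the
  recording: 1 definitely ... 4 certainly not.
* SSQ — subjective sleep quality: mean of the 8 "restedness" items
  (each 1-5) of the SF-A sleep questionnaire, i.e. sum/8, range 1-5.
* SSD — subjective sleep duration of the previous night, in minutes.

Group membership is the cross of two cut-offs: obese iff BMI >= 30
kg/m^2 and depressed iff BDI-II >= 14, giving HC / OB / DEP / OBDEP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .arousal import ArousalSummary

__all__ = [
    "GROUPS",
    "score_ess",
    "compute_ssq",
    "delta_scores",
    "classify_group",
    "QuestionnaireRecord",
    "Subject",
]

GROUPS = ("HC", "OB", "DEP", "OBDEP")

#: instrument value ranges used for validation
_RANGES = {
    "kss": (1, 10),
    "sss": (1, 7),
    "vas": (0, 100),
    "asleep": (1, 4),
}


class ValidationError(ValueError):
    """An out-of-range or malformed questionnaire value."""


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ValidationError(f"{name}={value!r} outside [{lo}, {hi}]")


def score_ess(items) -> tuple[int, bool]:
    """Score the Epworth Sleepiness Scale.

    Returns ``(total, eds)`` where total is the sum of the 8 items (0-24)
    and ``eds`` is True for totals above 10 (excessive daytime
    sleepiness).
    """
    items = list(items)
    if len(items) != 8:
        raise ValidationError(f"ESS needs 8 items, got {len(items)}")
    for i, item in enumerate(items):
        if int(item) != item:
            raise ValidationError(f"ESS item {i + 1} not an integer: {item!r}")
        _check_range(f"ESS item {i + 1}", item, 0, 3)
    total = int(sum(items))
    return total, total > 10


def compute_ssq(restedness_items) -> float:
    """Subjective sleep quality: sum of the 8 restedness items / 8.

    Each item is rated 1-5; higher SSQ means feeling more rested."""
    items = list(restedness_items)
    if len(items) != 8:
        raise ValidationError(f"restedness subscale needs 8 items, got {len(items)}")
    for i, item in enumerate(items):
        _check_range(f"restedness item {i + 1}", item, 1, 5)
    return sum(items) / 8.0


def delta_scores(pre: float, post: float, scale: str) -> float:
    """Post-minus-pre change score on a named scale ('kss', 'sss', 'vas')."""
    try:
        lo, hi = _RANGES[scale.lower()]
    except KeyError:
        raise ValidationError(f"unknown scale {scale!r}") from None
    _check_range(f"{scale} pre", pre, lo, hi)
    _check_range(f"{scale} post", post, lo, hi)
    return post - pre


def classify_group(bmi: float, bdi: float) -> str:
    """Four-way group label from BMI and BDI-II.

    Obese iff BMI >= 30 kg/m^2 (WHO cut-point); depressed iff
    BDI-II >= 14.  Partitions the whole (BMI, BDI) plane."""
    if bmi <= 0:
        raise ValidationError(f"BMI must be positive, got {bmi}")
    _check_range("BDI-II", bdi, 0, 63)
    obese = bmi >= 30.0
    depressed = bdi >= 14
    if obese and depressed:
        return "OBDEP"
    if obese:
        return "OB"
    if depressed:
        return "DEP"
    return "HC"


@dataclass(frozen=True)
class QuestionnaireRecord:
    """Validated subjective measures of one subject.

    Change scores (post - pre) are derived on construction and therefore
    always consistent with the raw values."""

    ess_items: tuple[int, ...]
    kss_pre: int
    kss_post: int
    sss_pre: int
    sss_post: int
    vas_pre: float
    vas_post: float
    asleep: int
    restedness_items: tuple[int, ...]
    ssd: float  # minutes

    def __post_init__(self) -> None:
        score_ess(self.ess_items)  # validates
        compute_ssq(self.restedness_items)
        for name in ("kss", "sss", "vas"):
            lo, hi = _RANGES[name]
            _check_range(f"{name}_pre", getattr(self, f"{name}_pre"), lo, hi)
            _check_range(f"{name}_post", getattr(self, f"{name}_post"), lo, hi)
        _check_range("asleep", self.asleep, 1, 4)
        if self.ssd < 0:
            raise ValidationError("sleep duration cannot be negative")
        object.__setattr__(self, "ess_items", tuple(self.ess_items))
        object.__setattr__(self, "restedness_items", tuple(self.restedness_items))

    @property
    def ess(self) -> int:
        return score_ess(self.ess_items)[0]

    @property
    def eds(self) -> bool:
        return score_ess(self.ess_items)[1]

    @property
    def ssq(self) -> float:
        return compute_ssq(self.restedness_items)

    @property
    def d_kss(self) -> int:
        return self.kss_post - self.kss_pre

    @property
    def d_sss(self) -> int:
        return self.sss_post - self.sss_pre

    @property
    def d_vas(self) -> float:
        return self.vas_post - self.vas_pre


@dataclass(frozen=True)
class Subject:
    """One participant: demographics, questionnaires, objective summary."""

    id: str
    age: float
    gender: str  # 'female' | 'male'
    bmi: float
    bdi: float
    questionnaire: QuestionnaireRecord
    arousal: ArousalSummary | None = None
    recording_seed: int | None = None

    def __post_init__(self) -> None:
        if self.gender not in ("female", "male"):
            raise ValidationError(f"gender must be female/male, got {self.gender!r}")
        if not 0 < self.age < 120:
            raise ValidationError(f"implausible age {self.age}")
        classify_group(self.bmi, self.bdi)  # validates

    @property
    def group(self) -> str:
        return classify_group(self.bmi, self.bdi)

    @property
    def depressed(self) -> bool:
        return self.bdi >= 14

    @property
    def obese(self) -> bool:
        return self.bmi >= 30.0

    def to_row(self) -> dict:
        """Flat analysis row (one subject) for the statistical battery."""
        q = self.questionnaire
        row = {
            "id": self.id,
            "age": self.age,
            "gender": self.gender,
            "bmi": self.bmi,
            "bdi": self.bdi,
            "group": self.group,
            "depressed": int(self.depressed),
            "obese": int(self.obese),
            "ess": q.ess,
            "eds": int(q.eds),
            "kss_pre": q.kss_pre,
            "kss_post": q.kss_post,
            "sss_pre": q.sss_pre,
            "sss_post": q.sss_post,
            "vas_pre": q.vas_pre,
            "vas_post": q.vas_post,
            "d_kss": q.d_kss,
            "d_sss": q.d_sss,
            "d_vas": q.d_vas,
            "asleep": q.asleep,
            "ssq": q.ssq,
            "ssd": q.ssd,
        }
        if self.arousal is not None:
            row.update(
                prop_0=self.arousal.prop_0,
                prop_a=self.arousal.prop_a,
                prop_b=self.arousal.prop_b,
                prop_c=self.arousal.prop_c,
                mvv=self.arousal.mvv,
                ass=self.arousal.ass,
            )
        return row
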