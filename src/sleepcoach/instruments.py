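"""Scoring of the self-report instruments the app administers.

Three instruments are scored here:

* the Insomnia Severity Index (ISI), a 7-item questionnaire (items 0..4)
  whose total (0..28) is banded into *none* (0-7), *subthreshold* (8-14),
  *moderate* (15-21) and *severe* (22-28) insomnia.  A total strictly above
  14 makes a user eligible for the behavioral intervention; a total strictly
  above 21 at the final interview indicates referral to a sleep specialist;
* the Acceptability E-scale (AES), yielding per-item mean *usability* and
  *satisfaction* subscores (satisfaction judged positive when > 3 out of 5);
* the agent trust questionnaire (ETQ), yielding *benevolence* (positive when
  the mean falls in the top-two agreement categories) and *credibility*
  (0..3 scale, positive when > 1).

Item lists of the AES/ETQ vary between deployments, so their subscale
layouts and scales are plain configuration objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum, IntEnum
from typing import Optional, Sequence, Tuple

__all__ = [
    "Occasion",
    "ISIBand",
    "ISIResponse",
    "ISIResult",
    "AESConfig",
    "AESResult",
    "ETQConfig",
    "ETQResult",
    "Familiarity",
    "score_isi",
    "classify_isi",
    "score_aes",
    "score_etq",
    "ISI_N_ITEMS",
    "ISI_ITEM_MAX",
    "ISI_TOTAL_MAX",
    "CLINICAL_THRESHOLD",
    "REFERRAL_THRESHOLD",
]

ISI_N_ITEMS = 7
ISI_ITEM_MIN = 0
ISI_ITEM_MAX = 4
ISI_TOTAL_MAX = ISI_N_ITEMS * ISI_ITEM_MAX  # 28

#: eligibility for the intervention program requires total > CLINICAL_THRESHOLD
CLINICAL_THRESHOLD = 14
#: persisting complaints at the final interview (total > REFERRAL_THRESHOLD)
#: indicate referral to a sleep specialist
REFERRAL_THRESHOLD = 21


class Occasion(str, Enum):
    """The three interview occasions on which the ISI is taken."""

    INTERVIEW1 = "interview1"
    INTERVIEW2 = "interview2"
    INTERVIEW3 = "interview3"

    @property
    def index(self) -> int:
        return {"interview1": 1, "interview2": 2, "interview3": 3}[self.value]


class ISIBand(str, Enum):
    """Severity bands of the ISI total score."""

    NONE = "none"  # 0-7: no clinically significant insomnia
    SUBTHRESHOLD = "subthreshold"  # 8-14
    MODERATE = "moderate"  # 15-21
    SEVERE = "severe"  # 22-28

    @classmethod
    def from_total(cls, total: int) -> "ISIBand":
        if total <= 7:
            return cls.NONE
        if total <= 14:
            return cls.SUBTHRESHOLD
        if total <= 21:
            return cls.MODERATE
        return cls.SEVERE


@dataclass(frozen=True)
class ISIResponse:
    """One administration of the 7 ISI items on a given occasion."""

    items: Tuple[int, ...]
    occasion: Occasion = Occasion.INTERVIEW1
    timestamp: Optional[datetime] = None

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        if len(items) != ISI_N_ITEMS:
            raise ValueError(
                f"ISI requires exactly {ISI_N_ITEMS} items, got {len(items)}"
            )
        for i, v in enumerate(items):
            if not (ISI_ITEM_MIN <= v <= ISI_ITEM_MAX):
                raise ValueError(
                    f"ISI item {i + 1} = {v} outside [{ISI_ITEM_MIN}, {ISI_ITEM_MAX}]"
                )
        object.__setattr__(self, "items", items)
        if not isinstance(self.occasion, Occasion):
            object.__setattr__(self, "occasion", Occasion(self.occasion))


@dataclass(frozen=True)
class ISIResult:
    """Scored ISI occasion: total, severity band and protocol flags."""

    total: int
    band: ISIBand
    eligible_for_intervention: bool
    referral_indicated: bool
    occasion: Optional[Occasion] = None


def classify_isi(total: int, occasion: Optional[Occasion] = None) -> ISIResult:
    """Band an ISI total and derive the eligibility / referral flags.

    Raises ``ValueError`` for totals outside [0, 28].
    """
    total = int(total)
    if not (0 <= total <= ISI_TOTAL_MAX):
        raise ValueError(f"ISI total {total} outside [0, {ISI_TOTAL_MAX}]")
    return ISIResult(
        total=total,
        band=ISIBand.from_total(total),
        eligible_for_intervention=total > CLINICAL_THRESHOLD,
        referral_indicated=total > REFERRAL_THRESHOLD,
        occasion=occasion,
    )


def score_isi(response: ISIResponse) -> ISIResult:
    """Score one ISI administration (total = sum of the 7 items)."""
    return classify_isi(sum(response.items), occasion=response.occasion)


# ---------------------------------------------------------------------------
# Acceptance (AES) and trust (ETQ) questionnaires
# ---------------------------------------------------------------------------


def _subscale_mean(
    items: Sequence[int],
    indices: Sequence[int],
    lo: int,
    hi: int,
    name: str,
) -> float:
    if not indices:
        raise ValueError(f"{name} subscale has no items configured")
    vals = []
    for i in indices:
        try:
            v = items[i]
        except IndexError as exc:
            raise ValueError(f"{name} subscale index {i} beyond item vector") from exc
        if not (lo <= v <= hi):
            raise ValueError(f"{name} item at index {i} = {v} outside [{lo}, {hi}]")
        vals.append(float(v))
    return sum(vals) / len(vals)


@dataclass(frozen=True)
class AESConfig:
    """Subscale layout of the Acceptability E-scale.

    Defaults: 6 items rated 1..5, the first three forming the usability
    subscale and the last three the satisfaction subscale.
    """

    usability_items: Tuple[int, ...] = (0, 1, 2)
    satisfaction_items: Tuple[int, ...] = (3, 4, 5)
    scale_min: int = 1
    scale_max: int = 5
    #: satisfaction judged positive when the per-item mean is strictly above
    #: this value (default: "more than 3 out of 5")
    satisfaction_threshold: float = 3.0


DEFAULT_AES = AESConfig()


@dataclass(frozen=True)
class AESResult:
    usability: float
    satisfaction: float
    n_items_per_subscale: int
    satisfaction_positive: bool


def score_aes(items: Sequence[int], config: AESConfig = DEFAULT_AES) -> AESResult:
    """Per-item mean usability and satisfaction subscores of the AES."""
    usability = _subscale_mean(
        items, config.usability_items, config.scale_min, config.scale_max, "usability"
    )
    satisfaction = _subscale_mean(
        items,
        config.satisfaction_items,
        config.scale_min,
        config.scale_max,
        "satisfaction",
    )
    return AESResult(
        usability=usability,
        satisfaction=satisfaction,
        n_items_per_subscale=len(config.usability_items),
        satisfaction_positive=satisfaction > config.satisfaction_threshold,
    )


@dataclass(frozen=True)
class ETQConfig:
    """Subscale layout of the agent trust questionnaire.

    Defaults: two benevolence items on a 5-level agreement scale (1 =
    totally disagree .. 5 = totally agree) and two credibility items on a
    0..3 scale.  Benevolence is positive when the mean sits in the top-two
    agreement levels (>= 4); credibility when strictly above 1 out of 3.
    """

    benevolence_items: Tuple[int, ...] = (0, 1)
    credibility_items: Tuple[int, ...] = (2, 3)
    benevolence_scale: Tuple[int, int] = (1, 5)
    credibility_scale: Tuple[int, int] = (0, 3)
    benevolence_positive_min: float = 4.0
    credibility_threshold: float = 1.0


DEFAULT_ETQ = ETQConfig()


@dataclass(frozen=True)
class ETQResult:
    benevolence: float
    credibility: float
    benevolence_positive: bool
    credibility_positive: bool


def score_etq(items: Sequence[int], config: ETQConfig = DEFAULT_ETQ) -> ETQResult:
    """Benevolence and credibility subscores of the trust questionnaire."""
    blo, bhi = config.benevolence_scale
    clo, chi = config.credibility_scale
    benevolence = _subscale_mean(items, config.benevolence_items, blo, bhi, "benevolence")
    credibility = _subscale_mean(items, config.credibility_items, clo, chi, "credibility")
    return ETQResult(
        benevolence=benevolence,
        credibility=credibility,
        benevolence_positive=benevolence >= config.benevolence_positive_min,
        credibility_positive=credibility > config.credibility_threshold,
    )


class Familiarity(IntEnum):
    """Single familiarity-with-technologies item (No / Moderately / Yes)."""

    NO = 0
    MODERATELY = 1
    YES = 2
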