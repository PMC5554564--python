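"""Evaluation utilities: cyclic durability loading and QUEST scoring.

Two quantitative evaluation procedures accompany the design pipeline.

**Durability load definition.**  The printed orthosis is fatigue-tested
under a sinusoidal stretching force at walking cadence.  The test is
specified by the standard fatigue quantities: stress ratio
``R = F_min / F_max`` (default 0.1), peak force ``F_max`` (default 50 N),
frequency (default 1 Hz) and cycle count (default 300,000).  One gait step
loads the orthosis once, so cycle counts convert directly to walking usage
(2,500 steps/day for 4 months of 30 days = 300,000 cycles).  The sampled
series starts at the valley (phase -pi/2) so every cycle attains its
minimum at its first sample and its maximum half a cycle later.

**QUEST.**  The Quebec User Evaluation of Satisfaction with Assistive
Technology device subscale: eight items (dimensions, weight, adjustment,
safety, durability, ease of use, comfort, effectiveness), each scored 1-5,
summarized as their mean rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import ParameterError

QUEST_ITEMS = (
    "dimensions",
    "weight",
    "adjustment",
    "safety",
    "durability",
    "ease_of_use",
    "comfort",
    "effectiveness",
)

DAYS_PER_MONTH = 30


@dataclass(frozen=True)
class LoadProfileSpec:
    """Sinusoidal fatigue-load parameters."""

    stress_ratio: float = 0.1
    peak_force_n: float = 50.0
    frequency_hz: float = 1.0
    cycle_count: int = 300_000
    samples_per_cycle: int = 32

    def validate(self) -> None:
        if not 0 <= self.stress_ratio < 1:
            raise ParameterError("stress_ratio must satisfy 0 <= R < 1")
        if self.peak_force_n <= 0:
            raise ParameterError("peak_force_n must be > 0")
        if self.frequency_hz <= 0:
            raise ParameterError("frequency_hz must be > 0")
        if self.cycle_count < 1:
            raise ParameterError("cycle_count must be >= 1")
        if self.samples_per_cycle < 4 or self.samples_per_cycle % 2:
            raise ParameterError("samples_per_cycle must be an even integer >= 4")

    @property
    def min_force_n(self) -> float:
        return self.stress_ratio * self.peak_force_n


@dataclass(frozen=True)
class QuestRecord:
    """Eight QUEST device-subscale item scores, each an integer in 1..5."""

    dimensions: int
    weight: int
    adjustment: int
    safety: int
    durability: int
    ease_of_use: int
    comfort: int
    effectiveness: int

    def __post_init__(self) -> None:
        for item in QUEST_ITEMS:
            score = getattr(self, item)
            if not isinstance(score, (int, np.integer)) or isinstance(score, bool):
                raise ParameterError(f"QUEST item '{item}' must be an integer")
            if not 1 <= score <= 5:
                raise ParameterError(
                    f"QUEST item '{item}' = {score} is outside the 1-5 scale"
                )

    @classmethod
    def from_scores(cls, scores) -> "QuestRecord":
        scores = list(scores)
        if len(scores) != len(QUEST_ITEMS):
            raise ParameterError(
                f"expected {len(QUEST_ITEMS)} QUEST scores, got {len(scores)}"
            )
        return cls(**dict(zip(QUEST_ITEMS, scores)))

    def scores(self) -> tuple:
        return tuple(getattr(self, item) for item in QUEST_ITEMS)


def cycles_from_usage(steps_per_day: int, days: int) -> int:
    """Load cycles equivalent to walking usage (one step = one cycle)."""
    if steps_per_day < 0 or days < 0:
        raise ParameterError("steps_per_day and days must be >= 0")
    return int(steps_per_day) * int(days)


def months_of_use(cycles: int, steps_per_day: int, days_per_month: int = DAYS_PER_MONTH) -> float:
    """Months of daily walking represented by a cycle count (30-day months)."""
    if cycles < 0 or steps_per_day <= 0 or days_per_month <= 0:
        raise ParameterError("cycles >= 0 and positive steps/day, days/month required")
    return cycles / (steps_per_day * days_per_month)


def load_profile(spec: LoadProfileSpec | None = None):
    """Sampled sinusoidal force series ``(time_s, force_n)``.

    ``F(t) = F_min + (F_max - F_min) * (1 + sin(2 pi f t - pi/2)) / 2``
    with ``F_min = R * F_max``; the series holds
    ``cycle_count * samples_per_cycle`` samples and attains the exact
    minimum and maximum once per cycle.
    """
    if spec is None:
        spec = LoadProfileSpec()
    spec.validate()
    per = spec.samples_per_cycle
    n = spec.cycle_count * per
    k = np.arange(n)
    t = k / (spec.frequency_hz * per)
    f_min = spec.min_force_n
    f_max = spec.peak_force_n
    # phase computed from k mod samples_per_cycle: the series is exactly
    # periodic and hits sin = -1 / +1 exactly at the valley/peak samples
    phase = 2.0 * np.pi * (k % per) / per - np.pi / 2.0
    force = f_min + (f_max - f_min) * (1.0 + np.sin(phase)) / 2.0
    return t, force


def quest_total(record: QuestRecord) -> float:
    """Mean of the eight item scores, rounded half-up to one decimal."""
    mean = Decimal(sum(record.scores())) / Decimal(len(QUEST_ITEMS))
    return float(mean.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
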