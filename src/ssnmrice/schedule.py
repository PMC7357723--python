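"""Growth-stage timing and split application of total N, P, K rates.

Fertilizer N goes out in three doses — early (within 11 days of crop
establishment), active tillering, and panicle initiation (PI) — normally as
24% / 38% / 38% of the total. When the crop reaches PI in under 30 days
after establishment (short-duration varieties transplanted with older
seedlings) the window between doses is too narrow for a small early dose to
matter, and three equal doses are used instead. All P and slightly more than
half of the K accompany the early N; the remaining K goes out at PI.

A fixed four-split blanket schedule (the regional blanket fertilizer
recommendation, BFR) is provided as the reference treatment.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, Field

from .agronomy import Establishment, NutrientRates, VarietyInfo

#: Default share of total N in each dose when PI is reached at >= 30 DAE.
N_SPLIT_FRACTIONS = (0.24, 0.38, 0.38)
#: Days after establishment from PI to physiological maturity; subtracted
#: from the in-field growth duration to place the PI dose.
PI_TO_MATURITY_OFFSET = 65
#: Default day for the early dose (must be <= 11 DAE).
EARLY_DOSE_DAY = 7
#: PI earlier than this (strict) switches N to three equal doses.
EQUAL_SPLIT_PI_THRESHOLD = 30

ROUND_STEP = 0.5  # kg ha-1; doses are repaired to conserve the total exactly


class Stage(str, Enum):
    EARLY = "early"
    ACTIVE_TILLERING = "active_tillering"
    PANICLE_INITIATION = "panicle_initiation"
    HEADING = "heading"


class ApplicationEvent(BaseModel):
    dae: int = Field(ge=0, description="days after establishment, day 0 = establishment")
    stage: Stage
    nutrients: NutrientRates


class ApplicationSchedule(BaseModel):
    events: list[ApplicationEvent]

    @property
    def n_applications(self) -> int:
        return len(self.events)

    def totals(self) -> NutrientRates:
        total = NutrientRates(n=0, p=0, k=0)
        for ev in self.events:
            total = total + ev.nutrients
        return total


def stage_days(variety: VarietyInfo, establishment: Establishment,
               seedling_age: int | None = None,
               pi_offset: int = PI_TO_MATURITY_OFFSET,
               early_day: int = EARLY_DOSE_DAY) -> tuple[int, int, int]:
    """Days after establishment for the early, tillering and PI doses.

    Transplanted rice spends ``seedling_age`` days in the nursery, so its
    in-field duration is the varietal duration minus the seedling age; direct
    seeded rice spends the whole duration in the field. PI is placed
    ``pi_offset`` days before maturity and active tillering midway between
    the early dose and PI (rounded down).
    """
    if establishment is Establishment.TRANSPLANTED:
        if seedling_age is None:
            raise ValueError("seedling_age required for transplanted rice")
        if seedling_age >= variety.duration:
            raise ValueError("seedling_age must be less than variety duration")
        in_field = variety.duration - seedling_age
    else:
        in_field = variety.duration
    dae_pi = in_field - pi_offset
    dae_tillering = (early_day + dae_pi) // 2
    return early_day, dae_tillering, dae_pi


def _round_conserving(doses: list[float], total: float) -> list[float]:
    """Round doses to ROUND_STEP with largest-remainder repair of the sum."""
    units = [d / ROUND_STEP for d in doses]
    floored = [int(u) for u in units]
    target_units = int(round(total / ROUND_STEP))
    short = target_units - sum(floored)
    # distribute the shortfall to the largest fractional remainders
    order = sorted(range(len(units)), key=lambda i: units[i] - floored[i], reverse=True)
    for i in order[:short]:
        floored[i] += 1
    return [f * ROUND_STEP for f in floored]


def split_n(total_n: float, dae_pi: int) -> list[float]:
    """Split total fertilizer N into three doses (early, tillering, PI).

    24/38/38 when PI falls at or after 30 days; three equal doses when PI is
    earlier. Doses are rounded to 0.5 kg and repaired so they sum exactly to
    the (0.5-kg-rounded) total.
    """
    if total_n < 0:
        raise ValueError("total_n must be non-negative")
    if dae_pi < EQUAL_SPLIT_PI_THRESHOLD:
        raw = [total_n / 3.0] * 3
    else:
        raw = [f * total_n for f in N_SPLIT_FRACTIONS]
    return _round_conserving(raw, total_n)


def split_pk(total_p: float, total_k: float,
             early_k_fraction: float = 0.55) -> tuple[tuple[float, float], float]:
    """Assign P and K to events: ((early P, early K), PI K).

    All P accompanies the early dose. K is split between the early dose and
    panicle initiation; the early share must lie in the practiced 50-58%
    window.
    """
    if not 0.50 <= early_k_fraction <= 0.58:
        raise ValueError("early_k_fraction must be within [0.50, 0.58]")
    early_k, pi_k = _round_conserving(
        [total_k * early_k_fraction, total_k * (1 - early_k_fraction)], total_k)
    return (total_p, early_k), pi_k


def build_schedule(rates: NutrientRates, days: tuple[int, int, int],
                   early_k_fraction: float = 0.55) -> ApplicationSchedule:
    """Compose the three-event schedule from total rates and stage days."""
    dae_early, dae_till, dae_pi = days
    if not dae_early <= 11:
        raise ValueError("early dose must fall within 11 days of establishment")
    n_doses = split_n(rates.n, dae_pi)
    (early_p, early_k), pi_k = split_pk(rates.p, rates.k, early_k_fraction)
    events = [
        ApplicationEvent(dae=dae_early, stage=Stage.EARLY,
                         nutrients=NutrientRates(n=n_doses[0], p=early_p, k=early_k)),
        ApplicationEvent(dae=dae_till, stage=Stage.ACTIVE_TILLERING,
                         nutrients=NutrientRates(n=n_doses[1], p=0, k=0)),
        ApplicationEvent(dae=dae_pi, stage=Stage.PANICLE_INITIATION,
                         nutrients=NutrientRates(n=n_doses[2], p=0, k=pi_k)),
    ]
    return ApplicationSchedule(events=events)


#: Blanket recommendation totals, kg ha-1 elemental.
BFR_RATES = NutrientRates(n=150.0, p=22.0, k=42.0)


def bfr_schedule(days: tuple[int, int, int, int] = (0, 21, 45, 72)) -> ApplicationSchedule:
    """The fixed blanket-recommendation schedule.

    150 kg N and 42 kg K ha-1 in four equal splits (basal, active tillering,
    panicle initiation, heading); all 22 kg P ha-1 basal.
    """
    n_dose = BFR_RATES.n / 4
    k_dose = BFR_RATES.k / 4
    stages = [Stage.EARLY, Stage.ACTIVE_TILLERING, Stage.PANICLE_INITIATION,
              Stage.HEADING]
    events = [
        ApplicationEvent(
            dae=d, stage=s,
            nutrients=NutrientRates(n=n_dose, p=BFR_RATES.p if i == 0 else 0.0,
                                    k=k_dose))
        for i, (d, s) in enumerate(zip(days, stages))
    ]
    return ApplicationSchedule(events=events)
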