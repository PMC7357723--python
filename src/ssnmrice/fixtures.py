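"""Synthetic interview records and on-farm trial populations.

Emulates the statistical structure of a multi-season on-farm trial series
in a double-cropped irrigated rice delta: per-season historical-yield
distributions (truncated normals), varietal baseline windows, season
calendars, farmer fertilizer-practice dispersion, and a yield model in
which each plot's yield is the smaller of the field's weather-limited
attainable yield and its N-supply-limited yield, plus plot noise.

The generator reproduces distributions and qualitative treatment contrasts,
not individual real fields; it carries no soil maps, weather series, or
pest/disease dynamics.
"""

from __future__ import annotations

import datetime

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import agronomy, engine, sources
from .agronomy import (
    Establishment,
    FieldInterview,
    IrrigationSource,
    NutrientRates,
    ResidueManagement,
    Season,
    SeasonParams,
    VarietyInfo,
)
from .economics import TrialRecord, Treatment
from .engine import ZINC_SULFATE_RATE, Recommendation
from .sources import Catalog


class TruncNormSpec(BaseModel):
    mean: float
    sd: float = Field(ge=0)
    lo: float
    hi: float

    @model_validator(mode="after")
    def _ordered(self) -> "TruncNormSpec":
        if self.lo >= self.hi:
            raise ValueError("truncation lo must be below hi")
        return self


class PopulationSpec(BaseModel):
    """Study conditions for one season's synthetic trial population."""

    season: Season
    n_fields: int = Field(gt=0)
    historical_yield: TruncNormSpec
    #: weather/establishment-limited attainable yield as a fraction of target
    attainment: TruncNormSpec
    #: farmer-practice rate dispersion, kg ha-1 (uniform ranges)
    ffp_n_range: tuple[float, float]
    ffp_p_range: tuple[float, float]
    ffp_k_range: tuple[float, float]
    #: realized agronomic efficiency of farmer-timed N, kg grain per kg N
    ffp_agronomic_efficiency: float = Field(default=12.0, gt=0)
    #: fraction of farmer plots with a fourth top dressing
    ffp_four_split_fraction: float = Field(default=0.69, ge=0, le=1)
    #: fraction of farmer plots applying zinc
    ffp_zinc_fraction: float = Field(default=0.14, ge=0, le=1)
    plot_noise_sd: float = Field(default=0.15, ge=0, description="Mg ha-1")
    sowing_window: tuple[datetime.date, datetime.date]
    transplant_delay: tuple[int, int] = (20, 30)  # days, nursery duration window
    duration_window: tuple[int, int]
    baseline_window: tuple[float, float]
    variety_name: str = "synthetic"
    prev_residue: ResidueManagement = ResidueManagement.REMOVED
    irrigation_source: IrrigationSource = IrrigationSource.CANAL
    field_area_range: tuple[float, float] = (0.2, 1.2)
    seed: int = 0


#: Shipped study conditions: 14 kuruvai, 40 samba and 20 thaladi fields with
#: the reported historical-yield distributions, varietal baseline windows
#: equal to the observed target ranges, and attainment distributions taken
#: from the measured yield-as-%-of-target statistics.
def default_population_specs(seed: int = 0) -> dict[Season, PopulationSpec]:
    return {
        Season.KURUVAI: PopulationSpec(
            season=Season.KURUVAI, n_fields=14,
            historical_yield=TruncNormSpec(mean=4.8, sd=0.8, lo=3.6, hi=6.1),
            attainment=TruncNormSpec(mean=0.98, sd=0.10, lo=0.78, hi=1.13),
            ffp_n_range=(92, 142), ffp_p_range=(10, 32), ffp_k_range=(24, 64),
            ffp_zinc_fraction=0.0,
            sowing_window=(datetime.date(2014, 6, 8), datetime.date(2014, 6, 23)),
            duration_window=(105, 110), baseline_window=(4.6, 6.1),
            irrigation_source=IrrigationSource.TUBE_WELL,
            seed=seed,
        ),
        Season.SAMBA: PopulationSpec(
            season=Season.SAMBA, n_fields=40,
            historical_yield=TruncNormSpec(mean=4.8, sd=0.8, lo=3.6, hi=6.4),
            attainment=TruncNormSpec(mean=0.91, sd=0.12, lo=0.57, hi=1.14),
            ffp_n_range=(92, 142), ffp_p_range=(10, 30), ffp_k_range=(33, 73),
            ffp_zinc_fraction=0.15,
            sowing_window=(datetime.date(2014, 8, 28), datetime.date(2014, 9, 30)),
            duration_window=(125, 135), baseline_window=(5.5, 6.9),
            irrigation_source=IrrigationSource.CANAL,
            seed=seed + 1,
        ),
        Season.THALADI: PopulationSpec(
            season=Season.THALADI, n_fields=20,
            historical_yield=TruncNormSpec(mean=4.4, sd=0.6, lo=3.6, hi=5.6),
            attainment=TruncNormSpec(mean=0.67, sd=0.14, lo=0.47, hi=1.00),
            ffp_n_range=(107, 157), ffp_p_range=(12, 32), ffp_k_range=(20, 60),
            ffp_zinc_fraction=0.20,
            sowing_window=(datetime.date(2014, 10, 8), datetime.date(2014, 11, 18)),
            duration_window=(125, 135), baseline_window=(5.2, 6.2),
            prev_residue=ResidueManagement.RETAINED_COMBINE,
            irrigation_source=IrrigationSource.RAIN_PLUS_CANAL,
            seed=seed + 2,
        ),
    }


def _truncnorm(rng: np.random.Generator, spec: TruncNormSpec, size: int) -> np.ndarray:
    """Rejection sampling from a truncated normal (exact, fast at these n)."""
    if spec.sd == 0:
        if not spec.lo <= spec.mean <= spec.hi:
            raise ValueError("degenerate truncated normal outside its range")
        return np.full(size, spec.mean)
    out = np.empty(size)
    filled = 0
    for _ in range(10000):
        draws = rng.normal(spec.mean, spec.sd, size=max(size, 16))
        keep = draws[(draws >= spec.lo) & (draws <= spec.hi)]
        take = min(len(keep), size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
        if filled == size:
            return out
    raise ValueError("truncation range has negligible mass under the normal")


def sample_interviews(spec: PopulationSpec,
                      rng: np.random.Generator | None = None) -> list[FieldInterview]:
    """Draw a season's worth of valid field interviews."""
    rng = rng or np.random.default_rng(spec.seed)
    hist = np.clip(_truncnorm(rng, spec.historical_yield, spec.n_fields), 3.0, 8.0)
    lo_date, hi_date = spec.sowing_window
    span = (hi_date - lo_date).days
    interviews = []
    for i in range(spec.n_fields):
        sowing = lo_date + datetime.timedelta(days=int(rng.integers(0, span + 1)))
        seedling_age = int(rng.integers(*spec.transplant_delay, endpoint=True))
        duration = int(rng.integers(*spec.duration_window, endpoint=True))
        interviews.append(FieldInterview(
            field_id=f"{spec.season.value}-{i + 1:03d}",
            field_area=float(np.round(rng.uniform(*spec.field_area_range), 2)),
            season=spec.season,
            irrigation_source=spec.irrigation_source,
            variety=VarietyInfo(name=spec.variety_name, duration=duration,
                                baseline_yield_lo=spec.baseline_window[0],
                                baseline_yield_hi=spec.baseline_window[1]),
            establishment=Establishment.TRANSPLANTED,
            seedling_age=seedling_age,
            sowing_date=sowing,
            establishment_date=sowing + datetime.timedelta(days=seedling_age),
            historical_yield=float(np.round(hist[i], 1)),
            prev_residue=spec.prev_residue,
            selected_products=["dap", "muriate_of_potash"],
        ))
    return interviews


def _ffp_masses(rates: NutrientRates, catalog: Catalog, zinc: bool) -> dict[str, float]:
    """Farmer-practice product masses, kg ha-1: DAP for P, MOP for K, urea rest."""
    masses: dict[str, float] = {}
    n_left = rates.n
    if rates.p > 0:
        dap = rates.p / catalog["dap"].p_frac
        masses["dap"] = round(dap, 1)
        n_left -= dap * catalog["dap"].n_frac
    if rates.k > 0:
        masses["muriate_of_potash"] = round(rates.k / catalog["muriate_of_potash"].k_frac, 1)
    if n_left > 0:
        masses["urea"] = round(n_left / catalog["urea"].n_frac, 1)
    if zinc:
        masses["zinc_sulfate"] = ZINC_SULFATE_RATE
    return masses


def _recommendation_masses(rec: Recommendation) -> dict[str, float]:
    """Per-hectare product masses implied by a recommendation's allocation."""
    names = {name for ev in rec.allocation.events for name, _ in ev.items}
    masses = {name: rec.allocation.total_mass(name) / rec.allocation.field_area
              for name in sorted(names)}
    masses["zinc_sulfate"] = ZINC_SULFATE_RATE
    return masses


def sample_population(
    spec: PopulationSpec,
    params: SeasonParams | None = None,
    catalog: Catalog | None = None,
) -> tuple[list[FieldInterview], list[TrialRecord]]:
    """Generate one season's interviews and simulated trial outcomes.

    Each field gets three plots (field-specific recommendation, farmer
    practice, blanket recommendation). Plot yield is
    min(attainable, N-limited) + noise, where attainable = target yield x a
    per-field attainment draw, and the N-limited yield is the indigenous-N
    yield plus the plot's N rate times a realized agronomic efficiency
    (lower for farmer-timed N than for stage-synchronized N).
    """
    params = params or agronomy.default_params(spec.season)
    catalog = catalog or sources.product_catalog_default()
    rng = np.random.default_rng(spec.seed)
    interviews = sample_interviews(spec, rng)
    attain = _truncnorm(rng, spec.attainment, spec.n_fields)

    records: list[TrialRecord] = []
    from .schedule import BFR_RATES, bfr_schedule  # local to avoid cycle at import

    bfr_alloc_masses: dict[str, float] = {}
    bfr = bfr_schedule()
    alloc = sources.allocate([(ev.dae, ev.nutrients) for ev in bfr.events],
                             ["dap", "muriate_of_potash"], catalog, field_area=1.0)
    for ev in alloc.events:
        for name, mass in ev.items:
            bfr_alloc_masses[name] = bfr_alloc_masses.get(name, 0.0) + mass
    bfr_alloc_masses["zinc_sulfate"] = ZINC_SULFATE_RATE

    for i, interview in enumerate(interviews):
        rec = engine.recommend(interview, catalog=catalog, params=params)
        target = rec.target_yield
        ywn = max(0.0, target - params.attainable_gain)
        attainable = target * attain[i]

        def plot_yield(n_applied: float, ae: float) -> float:
            supply_limited = ywn + ae * n_applied / 1000.0
            y = min(attainable, supply_limited) + rng.normal(0.0, spec.plot_noise_sd)
            return float(np.round(max(0.0, y), 2))

        records.append(TrialRecord(
            field_id=interview.field_id, season=spec.season,
            treatment=Treatment.NMR,
            grain_yield=plot_yield(rec.rates.n, params.agronomic_efficiency),
            rates=rec.rates,
            product_masses=_recommendation_masses(rec),
            n_applications=rec.schedule.n_applications,
            target_yield=target,
        ))

        ffp_rates = NutrientRates(
            n=float(np.round(rng.uniform(*spec.ffp_n_range))),
            p=float(np.round(rng.uniform(*spec.ffp_p_range))),
            k=float(np.round(rng.uniform(*spec.ffp_k_range))),
        )
        ffp_apps = 4 if rng.random() < spec.ffp_four_split_fraction else 3
        records.append(TrialRecord(
            field_id=interview.field_id, season=spec.season,
            treatment=Treatment.FFP,
            grain_yield=plot_yield(ffp_rates.n, spec.ffp_agronomic_efficiency),
            rates=ffp_rates,
            product_masses=_ffp_masses(ffp_rates, catalog,
                                       zinc=rng.random() < spec.ffp_zinc_fraction),
            n_applications=ffp_apps,
            target_yield=target,
        ))

        records.append(TrialRecord(
            field_id=interview.field_id, season=spec.season,
            treatment=Treatment.BFR,
            grain_yield=plot_yield(BFR_RATES.n, params.agronomic_efficiency),
            rates=BFR_RATES,
            product_masses=dict(bfr_alloc_masses),
            n_applications=bfr.n_applications,
            target_yield=target,
        ))
    return interviews, records
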