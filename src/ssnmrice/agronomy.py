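"""Field-specific target yield and fertilizer N, P, K rate calculation.

The core of site-specific nutrient management (SSNM) for irrigated rice:
a target yield is set for each field from the farmer's reported historical
yield and a varietal baseline window, the fertilizer N rate is derived from
the N-responsive yield gain via an agronomic-efficiency factor, the P rate
targets full maintenance of soil P (fertilizer input equals estimated crop
removal at the target yield), and the K rate targets partial maintenance
(crop removal less irrigation-water and crop-residue K inputs, less an
allowed drawdown of soil K reserves).
"""

from __future__ import annotations

import datetime
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator


class Season(str, Enum):
    """Irrigated rice seasons of the Cauvery Delta."""

    KURUVAI = "kuruvai"  # pre-monsoon, short-duration varieties
    SAMBA = "samba"  # single long rainy-season crop
    THALADI = "thaladi"  # second crop following kuruvai


class IrrigationSource(str, Enum):
    TUBE_WELL = "tube_well"
    CANAL = "canal"
    RAIN_PLUS_CANAL = "rain_plus_canal"


class Establishment(str, Enum):
    TRANSPLANTED = "transplanted"
    WET_SEEDED = "wet_seeded"
    DRY_SEEDED = "dry_seeded"


class ResidueManagement(str, Enum):
    """Fate of the previous crop's straw in this field."""

    REMOVED = "removed"
    RETAINED_COMBINE = "retained_combine"  # combine-harvested straw left in field


class VarietyInfo(BaseModel):
    """A rice variety: growth duration and its locally attainable yield window.

    The baseline window [baseline_yield_lo, baseline_yield_hi] is the range of
    yields the variety has achieved locally (expert knowledge and past trials);
    it bounds the target yield for any field growing this variety.
    """

    name: str
    duration: int = Field(ge=100, le=160, description="total growth duration, days")
    baseline_yield_lo: float = Field(gt=0)
    baseline_yield_hi: float = Field(gt=0)

    @model_validator(mode="after")
    def _window_ordered(self) -> "VarietyInfo":
        if self.baseline_yield_lo > self.baseline_yield_hi:
            raise ValueError("baseline_yield_lo must not exceed baseline_yield_hi")
        return self


class FieldInterview(BaseModel):
    """One farmer's pre-season answers — the sole field-specific input.

    historical_yield is grain at 14% moisture, Mg ha-1; the accepted window
    3.0-8.0 brackets the plausible reporting range for the region.
    """

    field_id: str = "field"
    field_area: float = Field(gt=0, description="ha")
    season: Season
    irrigation_source: IrrigationSource
    variety: VarietyInfo
    establishment: Establishment
    seedling_age: Optional[int] = Field(default=None, ge=5, le=60)
    sowing_date: datetime.date
    establishment_date: datetime.date
    historical_yield: float = Field(ge=3.0, le=8.0)
    prev_residue: ResidueManagement = ResidueManagement.REMOVED
    prev_crop_yield: Optional[float] = Field(
        default=None, gt=0,
        description="previous crop grain yield, Mg ha-1; defaults to historical_yield",
    )
    selected_products: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _consistency(self) -> "FieldInterview":
        if self.establishment is Establishment.TRANSPLANTED:
            if self.seedling_age is None:
                raise ValueError("seedling_age required for transplanted rice")
            if self.seedling_age >= self.variety.duration:
                raise ValueError("seedling_age must be less than variety duration")
        elif self.seedling_age is not None:
            raise ValueError("seedling_age only applies to transplanted rice")
        if self.establishment_date < self.sowing_date:
            raise ValueError("establishment_date must be on or after sowing_date")
        return self


class SeasonParams(BaseModel):
    """Per-season calibration of the rate equations.

    Removal coefficients are kg of nutrient removed per Mg of grain yield,
    split into a grain part (exported with harvested grain) and a straw part
    (exported only if straw leaves the field). Rice straw holds the large
    majority of above-ground plant K but a minor share of plant P, so
    straw_k_removal >> straw_p_removal.

    k_drawdown_target is the signed K balance the recommendation aims for at
    target yield; negative values permit mining of soil K reserves.
    """

    season: Season
    irrigation_k_input: float = Field(ge=0, description="kg K ha-1 per season")
    water_k_conc: float = Field(default=2.6, ge=0, description="mg K L-1, informative")
    k_drawdown_target: float = Field(description="kg K ha-1; negative = allowed mining")
    agronomic_efficiency: float = Field(gt=0, description="kg grain per kg fertilizer N")
    attainable_gain: float = Field(gt=0, description="N-responsive yield gain, Mg ha-1")
    target_increment: float = Field(default=1.0, ge=0, description="Mg ha-1")
    target_increment_max: float = Field(default=2.5, ge=0)
    late_establishment_cutoff: Optional[str] = Field(
        default=None, pattern=r"^\d{2}-\d{2}$",
        description="MM-DD; establishment after this date reduces the target",
    )
    late_penalty: float = Field(default=0.0, ge=0, description="Mg ha-1")
    grain_p_removal: float = Field(ge=0, description="kg P per Mg grain")
    straw_p_removal: float = Field(ge=0)
    grain_k_removal: float = Field(ge=0, description="kg K per Mg grain")
    straw_k_removal: float = Field(ge=0)
    residue_retention_efficiency: float = Field(default=0.8, ge=0, le=1)

    @model_validator(mode="after")
    def _checks(self) -> "SeasonParams":
        if self.target_increment > self.target_increment_max:
            raise ValueError("target_increment must not exceed target_increment_max")
        if self.straw_k_removal <= self.straw_p_removal:
            raise ValueError("straw K removal must exceed straw P removal")
        return self


class NutrientRates(BaseModel):
    """Elemental N, P, K in kg ha-1 — the engine's central intermediate."""

    n: float = Field(ge=0)
    p: float = Field(ge=0)
    k: float = Field(ge=0)

    def __add__(self, other: "NutrientRates") -> "NutrientRates":
        return NutrientRates(n=self.n + other.n, p=self.p + other.p, k=self.k + other.k)


# --- season defaults -------------------------------------------------------

#: Shipped per-season calibration. Irrigation K inputs of 25/8/4 kg ha-1
#: reflect tube-well, canal and rain-plus-canal water regimes at a mean water
#: K concentration of 2.6 mg L-1; K drawdown targets are -30/-33/-4 kg ha-1.
#: Removal coefficients: P 1.8 (grain) + 0.79 (straw) = 2.59 kg Mg-1 with the
#: straw holding ~30% of plant P; K 2.5 (grain) + 13.25 (straw) = 15.75
#: kg Mg-1 with the straw holding ~84% of plant K.
DEFAULT_SEASON_PARAMS: dict[Season, SeasonParams] = {
    Season.KURUVAI: SeasonParams(
        season=Season.KURUVAI,
        irrigation_k_input=25.0,
        k_drawdown_target=-30.0,
        agronomic_efficiency=15.0,
        attainable_gain=1.8,
        late_establishment_cutoff="06-15",
        late_penalty=0.5,
        grain_p_removal=1.8,
        straw_p_removal=0.79,
        grain_k_removal=2.5,
        straw_k_removal=13.25,
    ),
    Season.SAMBA: SeasonParams(
        season=Season.SAMBA,
        irrigation_k_input=8.0,
        k_drawdown_target=-33.0,
        agronomic_efficiency=15.0,
        attainable_gain=1.95,
        grain_p_removal=1.8,
        straw_p_removal=0.79,
        grain_k_removal=2.5,
        straw_k_removal=13.25,
    ),
    Season.THALADI: SeasonParams(
        season=Season.THALADI,
        irrigation_k_input=4.0,
        k_drawdown_target=-4.0,
        agronomic_efficiency=15.0,
        attainable_gain=1.95,
        grain_p_removal=1.8,
        straw_p_removal=0.79,
        grain_k_removal=2.5,
        straw_k_removal=13.25,
    ),
}


def default_params(season: Season | str) -> SeasonParams:
    """Return a copy of the shipped calibration for a season."""
    return DEFAULT_SEASON_PARAMS[Season(season)].model_copy(deep=True)


# --- removal helpers (single source of truth, shared with balances) --------

def p_removal(yield_mg: float, prev_residue: ResidueManagement,
              params: SeasonParams) -> float:
    """Estimated crop P removal, kg ha-1, at a given grain yield.

    When the previous crop's straw was retained, its P is recycled into the
    field, so the net straw export is scaled by (1 - retention efficiency).
    """
    straw_factor = (
        1.0 if prev_residue is ResidueManagement.REMOVED
        else 1.0 - params.residue_retention_efficiency
    )
    return yield_mg * (params.grain_p_removal + params.straw_p_removal * straw_factor)


def k_removal(yield_mg: float, params: SeasonParams) -> float:
    """Estimated crop K removal (grain + straw leaving the field), kg ha-1."""
    return yield_mg * (params.grain_k_removal + params.straw_k_removal)


def residue_k_input(interview: FieldInterview, params: SeasonParams) -> float:
    """K returned to the field by the previous crop's retained straw, kg ha-1."""
    if interview.prev_residue is not ResidueManagement.RETAINED_COMBINE:
        return 0.0
    prev_yield = interview.prev_crop_yield or interview.historical_yield
    return prev_yield * params.straw_k_removal * params.residue_retention_efficiency


# --- operations ------------------------------------------------------------

def set_target_yield(interview: FieldInterview, params: SeasonParams) -> float:
    """Set the target yield for a field, Mg ha-1.

    The reported historical yield plus a season increment, clamped to the
    variety's baseline window, then reduced by a late-establishment penalty
    where the season defines a cutoff date. The result is kept within
    [historical, historical + target_increment_max] so no field is asked to
    out-yield its own history by an implausible margin nor pushed below it.
    """
    if params.season is not interview.season:
        raise ConfigurationError(
            f"params are for {params.season.value}, interview is {interview.season.value}"
        )
    v = interview.variety
    target = interview.historical_yield + params.target_increment
    target = min(max(target, v.baseline_yield_lo), v.baseline_yield_hi)
    if params.late_establishment_cutoff is not None:
        month, day = map(int, params.late_establishment_cutoff.split("-"))
        cutoff = datetime.date(interview.establishment_date.year, month, day)
        if interview.establishment_date > cutoff:
            target -= params.late_penalty
    target = min(max(target, interview.historical_yield),
                 interview.historical_yield + params.target_increment_max)
    if target <= 0:
        raise ConfigurationError("target yield must be positive")
    return target


def n_rate(target_yield: float, yield_without_n: float, params: SeasonParams) -> float:
    """Fertilizer N rate, kg ha-1, from the yield-gain equation.

    N = 1000 * (target - yield without fertilizer N) / agronomic efficiency,
    rounded to the nearest 1 kg ha-1.
    """
    if params.agronomic_efficiency <= 0:
        raise ParameterError("agronomic_efficiency must be positive")
    if not 0 <= yield_without_n <= target_yield:
        raise ValueError("require 0 <= yield_without_n <= target_yield")
    gain = target_yield - yield_without_n
    return float(round(1000.0 * gain / params.agronomic_efficiency))


def p_rate(target_yield: float, prev_residue: ResidueManagement,
           params: SeasonParams) -> float:
    """Fertilizer P rate, kg ha-1: full maintenance of soil P.

    The rate equals estimated crop P removal at the target yield, so a field
    that achieves its target has a P balance of exactly zero.
    """
    if target_yield < 0:
        raise ValueError("target_yield must be non-negative")
    return float(round(p_removal(target_yield, prev_residue, params)))


def k_rate(target_yield: float, prev_residue: ResidueManagement,
           params: SeasonParams, residue_k: float = 0.0) -> float:
    """Fertilizer K rate, kg ha-1: partial maintenance of soil K.

    Crop K removal at target yield, less K supplied by irrigation water and
    retained crop residue, plus the (negative) targeted drawdown of soil K.
    Floored at zero when non-fertilizer inputs cover the requirement.
    """
    if target_yield < 0:
        raise ValueError("target_yield must be non-negative")
    rate = (k_removal(target_yield, params)
            - params.irrigation_k_input
            - residue_k
            + params.k_drawdown_target)
    return float(round(max(0.0, rate)))


class ConfigurationError(RuntimeError):
    """Missing or inconsistent season/variety configuration."""


class ParameterError(ValueError):
    """A calibration parameter is out of its valid domain."""
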