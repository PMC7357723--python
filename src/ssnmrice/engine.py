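"""End-to-end field recommendation: interview in, dated product plan out."""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel

from . import agronomy, schedule, sources
from .agronomy import FieldInterview, NutrientRates, SeasonParams
from .economics import EconParams
from .schedule import ApplicationSchedule
from .sources import Catalog, ProductAllocation

#: Fixed basal zinc line item, kg ha-1 of zinc sulfate. Field-specific zinc
#: diagnosis is not attempted; soils of the region are often low in
#: extractable zinc and a uniform basal dressing is recommended.
ZINC_SULFATE_RATE = 25.0


class Recommendation(BaseModel):
    """A complete, self-contained fertilizer recommendation for one field."""

    field_id: str
    season: str
    target_yield: float
    rates: NutrientRates
    schedule: ApplicationSchedule
    allocation: ProductAllocation
    zinc_sulfate_kg_field: float
    product_cost_usd: float
    labor_cost_usd_per_ha: float

    @property
    def n_applications(self) -> int:
        return self.schedule.n_applications


def recommend(interview: FieldInterview, catalog: Catalog | None = None,
              params: SeasonParams | None = None,
              econ: EconParams | None = None,
              yield_without_n: Optional[float] = None) -> Recommendation:
    """Compute the full field-specific recommendation for one interview.

    Composes target-yield setting, the N/P/K rate equations, the split
    schedule, and product allocation; product masses are scaled to the
    field's area. ``yield_without_n`` (the yield attainable on indigenous N
    supply alone) defaults to the target yield minus the season's attainable
    N-responsive gain.
    """
    catalog = catalog or sources.product_catalog_default()
    params = params or agronomy.default_params(interview.season)
    econ = econ or EconParams()

    target = agronomy.set_target_yield(interview, params)
    if yield_without_n is None:
        yield_without_n = max(0.0, target - params.attainable_gain)
    n = agronomy.n_rate(target, yield_without_n, params)
    p = agronomy.p_rate(target, interview.prev_residue, params)
    k = agronomy.k_rate(target, interview.prev_residue, params,
                        residue_k=agronomy.residue_k_input(interview, params))
    rates = NutrientRates(n=n, p=p, k=k)

    days = schedule.stage_days(interview.variety, interview.establishment,
                               interview.seedling_age)
    plan = schedule.build_schedule(rates, days)
    event_rates = [(ev.dae, ev.nutrients) for ev in plan.events]
    allocation = sources.allocate(event_rates, interview.selected_products,
                                  catalog, field_area=interview.field_area)
    zinc = ZINC_SULFATE_RATE * interview.field_area
    product_cost = allocation.product_cost(catalog)
    if "zinc_sulfate" in catalog:
        product_cost += zinc / 50.0 * catalog["zinc_sulfate"].price_per_50kg
    return Recommendation(
        field_id=interview.field_id,
        season=interview.season.value,
        target_yield=target,
        rates=rates,
        schedule=plan,
        allocation=allocation,
        zinc_sulfate_kg_field=zinc,
        product_cost_usd=product_cost,
        labor_cost_usd_per_ha=plan.n_applications * econ.labor_per_application,
    )
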