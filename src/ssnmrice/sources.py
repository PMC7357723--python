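"""Conversion of elemental nutrient rates into commercial fertilizer masses.

Allocation follows the fixed source-role policy used in practice: in the
early application, P is satisfied exactly by the first P-bearing product the
farmer selected, remaining K by the farmer's K source (muriate of potash if
none), and any remaining N by urea; N at tillering and panicle initiation is
always urea, and K at panicle initiation is always muriate of potash. No
least-cost blending is attempted.

Elemental fractions in the default catalog come from the standard grade
conversions P = P2O5 x 0.436 and K = K2O x 0.830.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .agronomy import NutrientRates

MASS_STEP = 0.1  # kg; internal rounding of product masses
TOLERANCE = 0.5  # kg ha-1 allowed nutrient shortfall/overshoot per event

UREA = "urea"
MOP = "muriate_of_potash"


class FertilizerProduct(BaseModel):
    name: str
    n_frac: float = Field(ge=0, le=1)
    p_frac: float = Field(ge=0, le=1)
    k_frac: float = Field(ge=0, le=1)
    price_per_50kg: float = Field(ge=0, description="US$ per 50 kg bag")

    @model_validator(mode="after")
    def _mass_fraction(self) -> "FertilizerProduct":
        if self.n_frac + self.p_frac + self.k_frac > 1:
            raise ValueError("elemental fractions cannot sum above 1")
        return self


class Catalog(BaseModel):
    products: dict[str, FertilizerProduct]

    def __getitem__(self, name: str) -> FertilizerProduct:
        try:
            return self.products[name]
        except KeyError:
            raise AllocationError(f"unknown fertilizer product: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.products

    @classmethod
    def from_csv(cls, path: str | Path) -> "Catalog":
        df = pd.read_csv(path)
        required = {"name", "n_frac", "p_frac", "k_frac", "price_per_50kg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"catalog CSV missing columns: {sorted(missing)}")
        products = {
            row["name"]: FertilizerProduct(**row)
            for row in df[sorted(required, key=list(df.columns).index)].to_dict("records")
        }
        return cls(products=products)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([p.model_dump() for p in self.products.values()]).to_csv(
            path, index=False,
            columns=["name", "n_frac", "p_frac", "k_frac", "price_per_50kg"])


def product_catalog_default() -> Catalog:
    """The locally available products with prevailing prices (US$ per 50 kg)."""
    rows = [
        FertilizerProduct(name=UREA, n_frac=0.46, p_frac=0.0, k_frac=0.0,
                          price_per_50kg=4.3),
        FertilizerProduct(name="dap", n_frac=0.18, p_frac=0.201, k_frac=0.0,
                          price_per_50kg=18.6),
        FertilizerProduct(name=MOP, n_frac=0.0, p_frac=0.0, k_frac=0.498,
                          price_per_50kg=12.7),
        FertilizerProduct(name="ssp", n_frac=0.0, p_frac=0.07, k_frac=0.0,
                          price_per_50kg=5.9),
        FertilizerProduct(name="17-17-17", n_frac=0.17, p_frac=0.074, k_frac=0.141,
                          price_per_50kg=14.3),
        FertilizerProduct(name="20-20-0", n_frac=0.20, p_frac=0.087, k_frac=0.0,
                          price_per_50kg=14.3),
        FertilizerProduct(name="zinc_sulfate", n_frac=0.0, p_frac=0.0, k_frac=0.0,
                          price_per_50kg=36.5),
    ]
    return Catalog(products={p.name: p for p in rows})


class EventAllocation(BaseModel):
    """Product masses (kg, for the whole field) for one application event."""

    dae: int
    items: list[tuple[str, float]]

    def mass_of(self, product: str) -> float:
        return sum(m for name, m in self.items if name == product)


class ProductAllocation(BaseModel):
    events: list[EventAllocation]
    field_area: float = Field(gt=0)
    shortfalls: NutrientRates = NutrientRates(n=0, p=0, k=0)

    def total_mass(self, product: str) -> float:
        return sum(ev.mass_of(product) for ev in self.events)

    def product_cost(self, catalog: Catalog) -> float:
        """Total product cost for the field, US$."""
        return sum(mass / 50.0 * catalog[name].price_per_50kg
                   for ev in self.events for name, mass in ev.items)

    def delivered(self, catalog: Catalog) -> NutrientRates:
        """Elemental nutrients delivered, kg ha-1 (all events combined)."""
        n = p = k = 0.0
        for ev in self.events:
            for name, mass in ev.items:
                prod = catalog[name]
                n += mass * prod.n_frac
                p += mass * prod.p_frac
                k += mass * prod.k_frac
        return NutrientRates(n=n / self.field_area, p=p / self.field_area,
                             k=k / self.field_area)


class AllocationError(RuntimeError):
    """Requested nutrients cannot be met from the available products."""


def _round_mass(mass: float) -> float:
    return round(mass / MASS_STEP) * MASS_STEP


def _first_with(selected: list[str], catalog: Catalog, nutrient: str) -> str | None:
    for name in selected:
        if getattr(catalog[name], nutrient) > 0:
            return name
    return None


def allocate(event_rates: list[tuple[int, NutrientRates]], selected: list[str],
             catalog: Catalog, field_area: float = 1.0) -> ProductAllocation:
    """Convert per-event elemental rates (kg ha-1) into product masses (kg/field).

    ``event_rates`` pairs each event's days-after-establishment with its
    NutrientRates. The first event is treated as the early application (the
    farmer's product choices apply there); all later events use urea for N
    and muriate of potash for K.
    """
    if UREA not in catalog or MOP not in catalog:
        raise AllocationError("catalog must include urea and muriate of potash")
    for name in selected:
        catalog[name]  # resolvable, raises otherwise

    events: list[EventAllocation] = []
    short_n = short_p = short_k = 0.0
    for idx, (dae, rates) in enumerate(event_rates):
        items: list[tuple[str, float]] = []
        need_n, need_p, need_k = rates.n, rates.p, rates.k
        if idx == 0:
            if need_p > 0:
                p_source = _first_with(selected, catalog, "p_frac")
                if p_source is None:
                    raise AllocationError(
                        "P requested but no P-bearing product selected")
                prod = catalog[p_source]
                mass = need_p / prod.p_frac
                items.append((p_source, mass))
                need_n -= mass * prod.n_frac
                need_k -= mass * prod.k_frac
                need_p = 0.0
            if need_k > TOLERANCE:
                k_source = _first_with(selected, catalog, "k_frac") or MOP
                prod = catalog[k_source]
                if prod.p_frac == 0 and prod.n_frac == 0:
                    mass = need_k / prod.k_frac
                    items.append((k_source, mass))
                    need_n -= mass * prod.n_frac
                    need_k = 0.0
                else:
                    # a compound K source would re-deliver P/N; fall back to MOP
                    mass = need_k / catalog[MOP].k_frac
                    items.append((MOP, mass))
                    need_k = 0.0
            if need_n > TOLERANCE:
                items.append((UREA, need_n / catalog[UREA].n_frac))
                need_n = 0.0
        else:
            if need_p > TOLERANCE:
                raise AllocationError("P can only be allocated in the early event")
            if need_k > TOLERANCE:
                items.append((MOP, need_k / catalog[MOP].k_frac))
                need_k = 0.0
            if need_n > TOLERANCE:
                items.append((UREA, need_n / catalog[UREA].n_frac))
                need_n = 0.0
        if need_n < -TOLERANCE or need_k < -TOLERANCE:
            warnings.warn(
                f"event at DAE {dae}: selected products oversupply nutrients "
                f"(N {max(0.0, -need_n):.1f}, K {max(0.0, -need_k):.1f} kg ha-1)",
                stacklevel=2)
        short_n += max(0.0, need_n)
        short_p += max(0.0, need_p)
        short_k += max(0.0, need_k)
        items = [(name, _round_mass(mass * field_area)) for name, mass in items
                 if mass > 0]
        events.append(EventAllocation(dae=dae, items=items))

    return ProductAllocation(
        events=events, field_area=field_area,
        shortfalls=NutrientRates(n=short_n, p=short_p, k=short_k))
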