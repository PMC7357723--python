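"""On-farm trial economics: fertilizer cost, PFP, returns and risk.

Per-field quantities: total fertilizer cost (product cost plus application
labor), partial factor productivity of fertilizer N (PFP = 1000 * GY / FN,
kg grain per kg N), gross return above fertilizer cost (grain value at the
minimum support price minus total fertilizer cost), and added net benefit
(difference in gross return above fertilizer cost between two treatments on
the same field). Risk across a trial population is summarized by empirical
exceedance curves of added net benefit and the probability of financial
loss.

Summaries compute per-field quantities first, then average — the order in
which on-farm trial series are normally analyzed.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .agronomy import NutrientRates, Season
from .sources import Catalog


class Treatment(str, Enum):
    NMR = "NMR"  # field-specific SSNM recommendation
    BFR = "BFR"  # blanket fertilizer recommendation
    FFP = "FFP"  # farmer's fertilizer practice
    NMR_PLUS_K = "NMR_plus_K"
    NMR_REFERENCE = "NMR_reference"


class TrialRecord(BaseModel):
    """One treatment plot of one on-farm trial."""

    field_id: str
    season: Season
    treatment: Treatment
    grain_yield: float = Field(ge=0, description="Mg ha-1 at 14% moisture")
    rates: NutrientRates
    product_masses: dict[str, float] = Field(
        default_factory=dict, description="kg ha-1 of each product")
    n_applications: int = Field(ge=0)
    target_yield: Optional[float] = Field(default=None, gt=0)


class EconParams(BaseModel):
    msp: float = Field(default=222.0, gt=0, description="support price, US$ per Mg")
    labor_per_application: float = Field(default=9.5, gt=0, description="US$ ha-1")
    exchange_rate: float = Field(default=63.0, gt=0, description="INR per US$")


class UndefinedPFPError(ZeroDivisionError):
    """PFP is undefined when no fertilizer N was applied."""


def total_fertilizer_cost(record: TrialRecord, catalog: Catalog,
                          econ: EconParams | None = None) -> float:
    """Product cost plus application labor, US$ ha-1."""
    econ = econ or EconParams()
    product_cost = sum(mass / 50.0 * catalog[name].price_per_50kg
                       for name, mass in record.product_masses.items())
    return product_cost + record.n_applications * econ.labor_per_application


def pfp(grain_yield: float, fertilizer_n: float) -> float:
    """Partial factor productivity of fertilizer N, kg grain per kg N."""
    if fertilizer_n <= 0:
        raise UndefinedPFPError("PFP requires fertilizer N > 0")
    return 1000.0 * grain_yield / fertilizer_n


def gross_return_above_fert(grain_yield: float, total_cost: float,
                            econ: EconParams | None = None) -> float:
    """Grain value at the support price minus total fertilizer cost, US$ ha-1."""
    econ = econ or EconParams()
    return grain_yield * econ.msp - total_cost


def added_net_benefit(grf_reference: float, grf_other: float) -> float:
    """Gain in gross return above fertilizer cost from switching treatments."""
    return grf_reference - grf_other


def percent_of_target(measured: float, target: float) -> float:
    """Measured yield as a percentage of the target yield."""
    if target <= 0:
        raise ValueError("target yield must be positive")
    return 100.0 * measured / target


def exceedance_curve(anb_values: Sequence[float],
                     thresholds: Sequence[float]) -> pd.Series:
    """Empirical probability that added net benefit reaches each threshold.

    P(ANB >= t), ties counted as exceeding; non-increasing in t.
    """
    values = np.asarray(anb_values, dtype=float)
    if values.size == 0:
        raise ValueError("anb_values must be non-empty")
    probs = [(values >= t).mean() for t in thresholds]
    return pd.Series(probs, index=list(thresholds), name="probability")


def loss_probability(anb_values: Sequence[float]) -> float:
    """Fraction of fields where the switch lost money (ANB < 0)."""
    values = np.asarray(anb_values, dtype=float)
    if values.size == 0:
        raise ValueError("anb_values must be non-empty")
    return float((values < 0).mean())


class EconomicSummary(BaseModel):
    """Per-treatment means and pairwise risk statistics for one population."""

    treatment_means: dict[str, dict[str, float]]  # treatment -> metric -> mean
    added_net_benefit_means: dict[str, float]  # "NMR-FFP" etc.
    loss_probabilities: dict[str, float]


def records_to_frame(records: Iterable[TrialRecord], catalog: Catalog,
                     econ: EconParams | None = None) -> pd.DataFrame:
    """Per-plot economics table: one row per (field, treatment)."""
    econ = econ or EconParams()
    rows = []
    for rec in records:
        cost = total_fertilizer_cost(rec, catalog, econ)
        grf = gross_return_above_fert(rec.grain_yield, cost, econ)
        rows.append({
            "field_id": rec.field_id,
            "season": rec.season.value,
            "treatment": rec.treatment.value,
            "grain_yield": rec.grain_yield,
            "n_rate": rec.rates.n,
            "p_rate": rec.rates.p,
            "k_rate": rec.rates.k,
            "n_applications": rec.n_applications,
            "total_cost": cost,
            "pfp": pfp(rec.grain_yield, rec.rates.n) if rec.rates.n > 0 else np.nan,
            "gross_return_above_fert": grf,
            "percent_of_target": (percent_of_target(rec.grain_yield, rec.target_yield)
                                  if rec.target_yield else np.nan),
        })
    return pd.DataFrame(rows)


def summarize(records: Iterable[TrialRecord], catalog: Catalog,
              econ: EconParams | None = None,
              reference: Treatment = Treatment.NMR) -> EconomicSummary:
    """Treatment means and pairwise added-net-benefit statistics.

    Added net benefit is computed per field (reference minus comparison on
    the same field) and then averaged, so its mean equals the difference of
    the treatment-mean gross returns over the common fields.
    """
    df = records_to_frame(records, catalog, econ)
    means: dict[str, dict[str, float]] = {}
    for trt, grp in df.groupby("treatment"):
        means[trt] = {
            "total_cost": round(grp["total_cost"].mean()),
            "grain_yield": round(grp["grain_yield"].mean(), 1),
            "pfp": round(grp["pfp"].mean()),
            "gross_return_above_fert": round(grp["gross_return_above_fert"].mean()),
        }
    anb_means: dict[str, float] = {}
    losses: dict[str, float] = {}
    wide = df.pivot_table(index="field_id", columns="treatment",
                          values="gross_return_above_fert")
    for other in (Treatment.FFP, Treatment.BFR):
        pair = f"{reference.value}-{other.value}"
        if reference.value in wide.columns and other.value in wide.columns:
            anb = (wide[reference.value] - wide[other.value]).dropna()
            if len(anb):
                anb_means[pair] = round(float(anb.mean()))
                losses[pair] = loss_probability(anb.to_numpy())
    return EconomicSummary(treatment_means=means,
                           added_net_benefit_means=anb_means,
                           loss_probabilities=losses)


def anb_per_field(records: Iterable[TrialRecord], catalog: Catalog,
                  econ: EconParams | None = None,
                  reference: Treatment = Treatment.NMR,
                  other: Treatment = Treatment.FFP) -> pd.Series:
    """Per-field added net benefit of ``reference`` over ``other``, US$ ha-1."""
    df = records_to_frame(records, catalog, econ)
    wide = df.pivot_table(index="field_id", columns="treatment",
                          values="gross_return_above_fert")
    if reference.value not in wide.columns or other.value not in wide.columns:
        raise ValueError(f"need both {reference.value} and {other.value} treatments")
    return (wide[reference.value] - wide[other.value]).dropna()


def read_trials_csv(path, catalog: Catalog | None = None) -> list[TrialRecord]:
    """Load a trial table CSV.

    Columns: field_id, season, treatment, grain_yield, n_rate, p_rate,
    k_rate, n_applications, plus optional ``product:<name>`` columns holding
    kg ha-1 of each fertilizer product.
    """
    df = pd.read_csv(path)
    records = []
    product_cols = [c for c in df.columns if c.startswith("product:")]
    for row in df.to_dict("records"):
        masses = {c.split(":", 1)[1]: float(row[c]) for c in product_cols
                  if not pd.isna(row[c]) and float(row[c]) > 0}
        records.append(TrialRecord(
            field_id=str(row["field_id"]), season=Season(row["season"]),
            treatment=Treatment(row["treatment"]),
            grain_yield=float(row["grain_yield"]),
            rates=NutrientRates(n=row["n_rate"], p=row["p_rate"], k=row["k_rate"]),
            product_masses=masses,
            n_applications=int(row["n_applications"]),
            target_yield=(float(row["target_yield"])
                          if "target_yield" in row and not pd.isna(row["target_yield"])
                          else None),
        ))
    return records


def trials_to_csv(records: Iterable[TrialRecord], path) -> None:
    records = list(records)
    product_names = sorted({name for r in records for name in r.product_masses})
    rows = []
    for r in records:
        row: dict = {
            "field_id": r.field_id, "season": r.season.value,
            "treatment": r.treatment.value, "grain_yield": r.grain_yield,
            "n_rate": r.rates.n, "p_rate": r.rates.p, "k_rate": r.rates.k,
            "n_applications": r.n_applications, "target_yield": r.target_yield,
        }
        for name in product_names:
            row[f"product:{name}"] = r.product_masses.get(name, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
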