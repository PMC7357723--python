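"""Post-hoc P and K input-output balances from achieved yields.

Balance = inputs (fertilizer, irrigation water, retained crop residue)
minus crop removal at the achieved yield. Irrigation water contributes K
but no P. Removal uses the same coefficients as the rate calculation, so a
field that achieves exactly its target yield under the field-specific
recommendation has a P balance of zero (full maintenance) and a K balance
equal to the season's targeted drawdown (partial maintenance).

Losses other than crop removal (leaching, runoff, gaseous) and organic
inputs other than rice residue are outside the accounting.
"""

from __future__ import annotations

from pydantic import BaseModel

from .agronomy import (
    FieldInterview,
    NutrientRates,
    ResidueManagement,
    SeasonParams,
    k_removal,
    p_removal,
)
from .agronomy import residue_k_input as _residue_k_input


class NutrientBalance(BaseModel):
    """Signed P and K balances, kg ha-1, with their components."""

    p_balance: float
    k_balance: float
    fertilizer_p: float
    fertilizer_k: float
    irrigation_k: float
    residue_k: float
    p_removal: float
    k_removal: float


def estimate_balance(rates: NutrientRates, achieved_yield: float,
                     params: SeasonParams,
                     prev_residue: ResidueManagement = ResidueManagement.REMOVED,
                     residue_k: float | None = None) -> NutrientBalance:
    """P and K balances for one plot given its fertilizer rates and yield.

    ``residue_k`` overrides the residue K input (kg ha-1) when known;
    otherwise it is zero for removed residue and must be supplied via
    :func:`balance_for_interview` for the retained-residue case, since it
    depends on the previous crop's yield.
    """
    if achieved_yield < 0:
        raise ValueError("achieved_yield must be non-negative")
    p_out = p_removal(achieved_yield, prev_residue, params)
    k_out = k_removal(achieved_yield, params)
    res_k = residue_k if residue_k is not None else 0.0
    return NutrientBalance(
        p_balance=rates.p - p_out,
        k_balance=rates.k + params.irrigation_k_input + res_k - k_out,
        fertilizer_p=rates.p,
        fertilizer_k=rates.k,
        irrigation_k=params.irrigation_k_input,
        residue_k=res_k,
        p_removal=p_out,
        k_removal=k_out,
    )


def balance_for_interview(interview: FieldInterview, rates: NutrientRates,
                          achieved_yield: float,
                          params: SeasonParams) -> NutrientBalance:
    """Balance for a field described by an interview (residue input derived)."""
    return estimate_balance(
        rates, achieved_yield, params, prev_residue=interview.prev_residue,
        residue_k=_residue_k_input(interview, params))
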