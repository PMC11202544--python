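"""Discounted test, diagnostic and treatment costs per pathway cell.

Cost timing follows the programme design: the triage test is paid for every
participant at the start (undiscounted); diagnostic imaging is incurred at
the moment of diagnosis, or at one year (the average over the two-year
programme) for participants who are investigated but never diagnosed;
treatment falls in the year of diagnosis.  Late-treated cases additionally
incur the confirmatory work-up of an out-of-programme diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outcomes import DiscountSpec, discount_amount
from .parameters import ModelInputs
from .tree import OutcomeClass, PathwayCell, PathwayClass, PathwayDistribution

__all__ = ["CostBreakdown", "cost_for_cell", "strategy_cost"]

#: discounting time for diagnostic costs of investigated-but-undiagnosed
#: participants: mid-programme of the two-year screening window
_MID_PROGRAMME_YEARS = 1.0


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted GBP per person in a cell, by component."""

    test: float | np.ndarray
    diagnostic: float | np.ndarray
    treatment: float | np.ndarray

    @property
    def total(self):
        return self.test + self.diagnostic + self.treatment


def cost_for_cell(
    cell: PathwayCell, mi: ModelInputs, disc: DiscountSpec
) -> CostBreakdown:
    """Per-person discounted cost components for one pathway cell.

    ``mi`` must already carry the strategy's test cost (see
    :func:`lungscreen.parameters.apply_strategy`); the cells of a
    :class:`PathwayDistribution` come paired with such a realisation.
    """
    pw, out = cell.pathway, cell.outcome
    dx = cell.diagnosis_time

    test = mi.test_cost + 0.0  # applied to every participant at t = 0

    diagnostic = 0.0
    if pw is PathwayClass.TP:
        diagnostic = discount_amount(mi.diag_tp_fp, dx, disc)
    elif pw is PathwayClass.FP:
        diagnostic = discount_amount(mi.diag_tp_fp, dx, disc)
    elif pw is PathwayClass.TP_NOT_LDCT:
        diagnostic = discount_amount(mi.diag_tp_noldct, dx, disc)
    elif pw is PathwayClass.TN_LDCT:
        diagnostic = discount_amount(
            mi.diag_tn_fn_ldct, _MID_PROGRAMME_YEARS, disc
        )
    elif pw is PathwayClass.FN_LDCT:
        diagnostic = discount_amount(
            mi.diag_tn_fn_ldct, _MID_PROGRAMME_YEARS, disc
        )
        if out is OutcomeClass.LS_LATE_TREATED:
            diagnostic = diagnostic + discount_amount(mi.diag_tp_noldct, dx, disc)
    elif pw is PathwayClass.FN and out is OutcomeClass.LS_LATE_TREATED:
        # diagnosed outside the programme in order to be treated
        diagnostic = discount_amount(mi.diag_tp_noldct, dx, disc)
    # TN and never-treated FN are never investigated: zero

    treatment = 0.0
    if out is OutcomeClass.ES_DETECTED:
        # early treatment now plus late-stage treatment for the recurring
        # fraction (no recurrence delay is modelled, which slightly
        # overstates its present value)
        treatment = discount_amount(
            mi.treat_es + mi.prop_es_recur * mi.treat_ls, dx, disc
        )
    elif out in (OutcomeClass.LS_DETECTED, OutcomeClass.LS_LATE_TREATED):
        treatment = discount_amount(mi.treat_ls, dx, disc)

    return CostBreakdown(test, diagnostic, treatment)


def strategy_cost(
    dist: PathwayDistribution, disc: DiscountSpec, cohort_size: float
) -> dict:
    """Expected discounted cost per cohort, with component breakdown.

    Returns ``{"test", "diagnostic", "treatment", "total"}`` in GBP per
    ``cohort_size`` participants (scalar or per-draw arrays).
    """
    comp = {"test": 0.0, "diagnostic": 0.0, "treatment": 0.0}
    for cell in dist.cells:
        cb = cost_for_cell(cell, dist.inputs, disc)
        comp["test"] = comp["test"] + cell.probability * cb.test
        comp["diagnostic"] = comp["diagnostic"] + cell.probability * cb.diagnostic
        comp["treatment"] = comp["treatment"] + cell.probability * cb.treatment
    out = {k: v * cohort_size for k, v in comp.items()}
    out["total"] = out["test"] + out["diagnostic"] + out["treatment"]
    return out


def cost_table(dist: PathwayDistribution, disc: DiscountSpec,
               cohort_size: float) -> pd.DataFrame:
    """Per-strategy component breakdown as a tidy frame (for CSV export)."""
    comps = strategy_cost(dist, disc, cohort_size)
    return pd.DataFrame(
        [
            {"strategy": dist.strategy.name, "component": k,
             "discounted_gbp_per_cohort": float(v)}
            for k, v in comps.items()
        ]
    )
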