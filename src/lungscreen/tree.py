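"""Decision tree: joint pathway/outcome probabilities for one strategy.

The screened cohort branches on true disease state (no cancer, early stage,
late stage), the triage blood-test result, the 6-monthly LDCT programme for
test-positives, and opportunistic detection through routine care for
test-negative cases.  Each leaf is a :class:`PathwayCell` carrying a
diagnostic-pathway label, a stage-at-detection outcome, a joint probability
and a diagnosis time.

Undetected early-stage cancer progresses to late stage; never-screen-
detected late-stage mass splits into a treated fraction (diagnosed late,
immunotherapy-era survival) and a never-treated remainder (pre-
immunotherapy survival, no treatment cost).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .parameters import ModelInputs, StrategyConfig, apply_strategy

__all__ = [
    "PathwayClass",
    "OutcomeClass",
    "PathwayCell",
    "PathwayDistribution",
    "pathway_distribution",
    "expected_counts",
    "es_detected",
]


class PathwayClass(str, Enum):
    """Diagnostic pathway followed by a participant."""

    TP = "TP"
    TP_NOT_LDCT = "TP_NOT_LDCT"
    TN = "TN"
    TN_LDCT = "TN_LDCT"
    FP = "FP"
    FN = "FN"
    FN_LDCT = "FN_LDCT"


class OutcomeClass(str, Enum):
    """Lung-cancer status and stage at (eventual) detection."""

    NOLC = "NOLC"
    NOLC_FP = "NOLC_FP"
    ES_DETECTED = "ES_DETECTED"
    LS_DETECTED = "LS_DETECTED"
    LS_LATE_TREATED = "LS_LATE_TREATED"
    LS_NEVER_TREATED = "LS_NEVER_TREATED"


#: outcomes that represent lung-cancer cases
LC_OUTCOMES = (
    OutcomeClass.ES_DETECTED,
    OutcomeClass.LS_DETECTED,
    OutcomeClass.LS_LATE_TREATED,
    OutcomeClass.LS_NEVER_TREATED,
)


@dataclass(frozen=True)
class PathwayCell:
    pathway: PathwayClass
    outcome: OutcomeClass
    probability: float | np.ndarray
    #: years from start of screening to diagnosis; None when never diagnosed
    #: and never investigated
    diagnosis_time: float | np.ndarray | None
    #: true stage during the screening window ("ES", "LS" or None)
    origin_stage: str | None = None


@dataclass(frozen=True)
class PathwayDistribution:
    strategy: StrategyConfig
    inputs: ModelInputs  # strategy-applied realisation the cells came from
    cells: tuple[PathwayCell, ...]

    def total_probability(self):
        return sum(c.probability for c in self.cells)


def _late_split(mass, mi: ModelInputs, pathway: PathwayClass, origin: str):
    """Split undetected cancer mass into late-treated and never-treated."""
    t = mi.leadtime_ls
    return (
        PathwayCell(pathway, OutcomeClass.LS_LATE_TREATED,
                    mass * mi.prop_fn_treated, t, origin),
        PathwayCell(pathway, OutcomeClass.LS_NEVER_TREATED,
                    mass * (1.0 - mi.prop_fn_treated), t, origin),
    )


def pathway_distribution(
    params: ModelInputs, strategy: StrategyConfig
) -> PathwayDistribution:
    """Enumerate every (pathway, outcome) cell for one strategy.

    Works elementwise on array-valued inputs, so a single call evaluates
    every PSA draw at once.
    """
    mi = apply_strategy(params, strategy)
    p, pes = mi.prevalence, mi.prevalence_early
    cells: list[PathwayCell] = []

    # --- early-stage cancer ------------------------------------------------
    m = p * pes
    cells.append(
        PathwayCell(PathwayClass.TP, OutcomeClass.ES_DETECTED,
                    m * mi.sens_es * mi.ldct_sens, mi.leadtime_es, "ES")
    )
    cells.extend(
        _late_split(m * mi.sens_es * (1.0 - mi.ldct_sens), mi,
                    PathwayClass.FN_LDCT, "ES")
    )
    cells.append(
        PathwayCell(PathwayClass.TP_NOT_LDCT, OutcomeClass.ES_DETECTED,
                    m * (1.0 - mi.sens_es) * mi.op_es, mi.leadtime_es, "ES")
    )
    cells.extend(
        _late_split(m * (1.0 - mi.sens_es) * (1.0 - mi.op_es), mi,
                    PathwayClass.FN, "ES")
    )

    # --- late-stage cancer -------------------------------------------------
    m = p * (1.0 - pes)
    cells.append(
        PathwayCell(PathwayClass.TP, OutcomeClass.LS_DETECTED,
                    m * mi.sens_ls * mi.ldct_sens, mi.leadtime_ls, "LS")
    )
    cells.extend(
        _late_split(m * mi.sens_ls * (1.0 - mi.ldct_sens), mi,
                    PathwayClass.FN_LDCT, "LS")
    )
    cells.append(
        PathwayCell(PathwayClass.TP_NOT_LDCT, OutcomeClass.LS_DETECTED,
                    m * (1.0 - mi.sens_ls) * mi.op_ls, mi.leadtime_ls, "LS")
    )
    cells.extend(
        _late_split(m * (1.0 - mi.sens_ls) * (1.0 - mi.op_ls), mi,
                    PathwayClass.FN, "LS")
    )

    # --- no cancer ---------------------------------------------------------
    m = 1.0 - p
    cells.append(
        PathwayCell(PathwayClass.TN_LDCT, OutcomeClass.NOLC,
                    m * (1.0 - mi.spec) * mi.ldct_spec, None, None)
    )
    # false positives (only when LDCT specificity < 1): investigated and
    # worked up mid-programme, never treated
    cells.append(
        PathwayCell(PathwayClass.FP, OutcomeClass.NOLC_FP,
                    m * (1.0 - mi.spec) * (1.0 - mi.ldct_spec), 1.0, None)
    )
    cells.append(
        PathwayCell(PathwayClass.TN, OutcomeClass.NOLC, m * mi.spec, None, None)
    )

    return PathwayDistribution(strategy, mi, tuple(cells))


def expected_counts(dist: PathwayDistribution, cohort_size: float) -> pd.DataFrame:
    """Expected participants per cell: ``probability * cohort_size``.

    Only meaningful for scalar-valued distributions.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be > 0")
    rows = [
        {
            "strategy": dist.strategy.name,
            "pathway": c.pathway.value,
            "outcome": c.outcome.value,
            "origin_stage": c.origin_stage,
            "probability": float(c.probability),
            "expected_count": float(c.probability) * cohort_size,
            "diagnosis_time": None if c.diagnosis_time is None
            else float(c.diagnosis_time),
        }
        for c in dist.cells
    ]
    return pd.DataFrame(rows)


def es_detected(dist: PathwayDistribution):
    """Probability mass detected at early stage (screen or opportunistic)."""
    return sum(
        c.probability for c in dist.cells if c.outcome is OutcomeClass.ES_DETECTED
    )
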