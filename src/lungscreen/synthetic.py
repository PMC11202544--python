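"""Individual-level synthetic cohorts with the model's statistical structure.

Serves two validation purposes: a microsimulation oracle for the
expectation tree (sampling every chance node instead of multiplying
probabilities), and parameter-recovery fixtures for each estimated
quantity — test accuracy and opportunistic-detection proportions
(Bernoulli), lead times (gamma), utilities (beta) and survival (Weibull
with administrative censoring, Kaplan–Meier estimable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.special import gamma as _gamma_fn

from .outcomes import DiscountSpec, KMPoint, WeibullModel, qaly_for_cell
from .costs import cost_for_cell
from .parameters import (
    EvaluationSettings,
    ParameterSet,
    StrategyConfig,
    apply_strategy,
    make_strategy,
)
from .tree import OutcomeClass, PathwayCell, PathwayClass

__all__ = [
    "SyntheticCohortSpec",
    "simulate_cohort",
    "estimate_parameters",
    "microsim_evaluate",
    "simulate_km_points",
]

#: Weibull shape used for synthetic survival fixtures (scale is set so the
#: mean matches the stage life expectancy)
FIXTURE_WEIBULL_SHAPE = 1.2


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_per_arm: int
    params: ParameterSet
    strategy: StrategyConfig | None = None  # intervention arm; default ecls
    censoring_time: float = 10.0
    rng_seed: int = 0
    #: optional disease-prevalence override used to enrich cancer cases for
    #: estimator tests at realistic sizes; never used in evaluation
    enrich_prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")


def _survival_scale(mean_years: float) -> float:
    return mean_years / float(_gamma_fn(1.0 + 1.0 / FIXTURE_WEIBULL_SHAPE))


def _simulate_arm(
    spec: SyntheticCohortSpec, arm: str, strategy: StrategyConfig,
    rng: np.random.Generator
) -> pd.DataFrame:
    mi = apply_strategy(spec.params.base(), strategy)
    if spec.enrich_prevalence is not None:
        mi = mi.replace(prevalence=spec.enrich_prevalence)
    n = spec.n_per_arm

    # true disease state
    u = rng.random(n)
    es = u < mi.prevalence * mi.prevalence_early
    ls = (~es) & (u < mi.prevalence)
    disease = np.where(es, "ES", np.where(ls, "LS", "none"))

    # triage test
    p_pos = np.where(es, mi.sens_es, np.where(ls, mi.sens_ls, 1.0 - mi.spec))
    test_pos = rng.random(n) < p_pos

    # LDCT programme for test-positives
    p_ldct_pos = np.where(disease == "none", 1.0 - mi.ldct_spec, mi.ldct_sens)
    ldct_pos = test_pos & (rng.random(n) < p_ldct_pos)

    # opportunistic detection for test-negative cancers
    p_op = np.where(es, mi.op_es, np.where(ls, mi.op_ls, 0.0))
    opportunistic = (~test_pos) & (disease != "none") & (rng.random(n) < p_op)

    late_treated = rng.random(n) < mi.prop_fn_treated

    diseased = disease != "none"
    pathway = np.select(
        [
            diseased & test_pos & ldct_pos,
            diseased & test_pos & ~ldct_pos,
            diseased & ~test_pos & opportunistic,
            diseased & ~test_pos & ~opportunistic,
            ~diseased & test_pos & ldct_pos,
            ~diseased & test_pos & ~ldct_pos,
        ],
        [
            PathwayClass.TP.value,
            PathwayClass.FN_LDCT.value,
            PathwayClass.TP_NOT_LDCT.value,
            PathwayClass.FN.value,
            PathwayClass.FP.value,
            PathwayClass.TN_LDCT.value,
        ],
        default=PathwayClass.TN.value,
    )

    screen_detected = diseased & ((test_pos & ldct_pos) | opportunistic)
    undetected = diseased & ~screen_detected
    outcome = np.select(
        [
            es & screen_detected,
            ls & screen_detected,
            undetected & late_treated,
            undetected & ~late_treated,
            ~diseased & test_pos & ldct_pos,
        ],
        [
            OutcomeClass.ES_DETECTED.value,
            OutcomeClass.LS_DETECTED.value,
            OutcomeClass.LS_LATE_TREATED.value,
            OutcomeClass.LS_NEVER_TREATED.value,
            OutcomeClass.NOLC_FP.value,
        ],
        default=OutcomeClass.NOLC.value,
    )

    # lead times: early-stage detections use the short lead-time gamma,
    # every late-stage course (detected or not) the long one
    lt = np.full(n, np.nan)
    early = outcome == OutcomeClass.ES_DETECTED.value
    late = diseased & ~early
    g_es = spec.params["leadtime_es"].dist
    g_ls = spec.params["leadtime_ls"].dist
    lt[early] = g_es.sample(rng, int(early.sum()), mi.leadtime_es)
    lt[late] = g_ls.sample(rng, int(late.sum()), mi.leadtime_ls)

    utility = spec.params["u_nolc"].dist.sample(rng, n, mi.u_nolc)

    # survival from diagnosis, Weibull with administrative censoring
    surv = np.full(n, np.nan)
    cens = np.zeros(n, dtype=bool)
    means = {
        OutcomeClass.ES_DETECTED.value: 0.5 * (mi.le_stage_i + mi.le_stage_ii),
        OutcomeClass.LS_DETECTED.value: 0.5
        * (mi.le_stage_iii_immuno + mi.le_stage_iv_immuno),
        OutcomeClass.LS_LATE_TREATED.value: 0.5
        * (mi.le_stage_iii_immuno + mi.le_stage_iv_immuno),
        OutcomeClass.LS_NEVER_TREATED.value: 0.5
        * (mi.le_stage_iii_prior + mi.le_stage_iv_prior),
    }
    for oc, mean in means.items():
        mask = outcome == oc
        k = int(mask.sum())
        if k:
            t = _survival_scale(mean) * rng.weibull(FIXTURE_WEIBULL_SHAPE, k)
            censored = t > spec.censoring_time
            surv[mask] = np.minimum(t, spec.censoring_time)
            cens[mask] = censored

    test_result = np.where(
        strategy.name == "no_screening",
        "not_administered",
        np.where(test_pos, "positive", "negative"),
    )
    ldct_result = np.where(
        test_pos & (strategy.name != "no_screening"),
        np.where(ldct_pos, "positive", "negative"),
        "not_done",
    )

    return pd.DataFrame(
        {
            "arm": arm,
            "disease": disease,
            "test_result": test_result,
            "ldct_result": ldct_result,
            "opportunistic": opportunistic,
            "pathway": pathway,
            "outcome": outcome,
            "lead_time": lt,
            "utility": utility,
            "survival_time": surv,
            "censored": cens,
        }
    )


def simulate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Two-arm individual-level cohort, one row per participant.

    The intervention arm follows ``spec.strategy`` (blood-test triage by
    default); the control arm follows the no-screening comparator.
    """
    rng = np.random.default_rng(spec.rng_seed)
    strategy = spec.strategy or make_strategy("ecls")
    frames = [
        _simulate_arm(spec, "intervention", strategy, rng),
        _simulate_arm(spec, "control", make_strategy("no_screening"), rng),
    ]
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", np.arange(len(out)))
    return out


def _prop(mask_num: pd.Series, mask_den: pd.Series):
    n = int(mask_den.sum())
    if n == 0:
        return None
    k = int((mask_num & mask_den).sum())
    p = k / n
    return {"estimate": p, "se": math.sqrt(max(p * (1 - p), 1e-300) / n), "n": n}


def _mean(values: pd.Series):
    x = values.dropna().to_numpy()
    if x.size == 0:
        return None
    se = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0
    return {"estimate": float(np.mean(x)), "se": se, "n": int(x.size)}


def estimate_parameters(records: pd.DataFrame) -> dict:
    """Plug-in estimates of the trial-estimated parameters.

    Sensitivity and specificity come from the intervention arm (test
    administered); opportunistic-detection rates from the control arm,
    where every cancer detected within the window is by definition
    opportunistic.  Empty strata yield ``None`` rather than zero.
    """
    iv = records[records["arm"] == "intervention"]
    ct = records[records["arm"] == "control"]
    tested = iv[iv["test_result"] != "not_administered"]

    est: dict = {}
    est["sens_es"] = _prop(
        tested["test_result"] == "positive", tested["disease"] == "ES"
    )
    est["sens_ls"] = _prop(
        tested["test_result"] == "positive", tested["disease"] == "LS"
    )
    est["spec"] = _prop(
        tested["test_result"] == "negative", tested["disease"] == "none"
    )
    est["op_es"] = _prop(ct["opportunistic"], ct["disease"] == "ES")
    est["op_ls"] = _prop(ct["opportunistic"], ct["disease"] == "LS")
    diagnosed_es = records["outcome"] == OutcomeClass.ES_DETECTED.value
    late = records["outcome"].isin(
        [
            OutcomeClass.LS_DETECTED.value,
            OutcomeClass.LS_LATE_TREATED.value,
            OutcomeClass.LS_NEVER_TREATED.value,
        ]
    )
    est["leadtime_es"] = _mean(records.loc[diagnosed_es, "lead_time"])
    est["leadtime_ls"] = _mean(records.loc[late, "lead_time"])
    est["u_nolc"] = _mean(records["utility"])
    return est


def microsim_evaluate(
    records: pd.DataFrame,
    params: ParameterSet,
    settings: EvaluationSettings | None = None,
    strategy: StrategyConfig | None = None,
) -> pd.DataFrame:
    """Per-arm empirical mean cost and QALYs, assembled person by person
    with the same cost/QALY engines as the expectation tree.

    Each participant's drawn lead time and utility enter their own cell
    evaluation, so the arm means converge (law of large numbers) to the
    tree's expected values — the brute-force oracle for
    :func:`lungscreen.evaluate.evaluate_strategy`.
    """
    settings = settings or EvaluationSettings()
    disc = DiscountSpec(settings.discount_rate, settings.discount_free_years)
    strategy = strategy or make_strategy("ecls")
    rows = []
    for arm, grp in records.groupby("arm"):
        arm_strategy = (
            strategy if arm == "intervention" else make_strategy("no_screening")
        )
        mi_arm = apply_strategy(params.base(), arm_strategy)
        cost = np.zeros(len(grp))
        qaly = np.zeros(len(grp))
        for (pw, oc), sub in grp.groupby(["pathway", "outcome"]):
            idx = grp.index.get_indexer(sub.index)
            outcome = OutcomeClass(oc)
            lc = outcome not in (OutcomeClass.NOLC, OutcomeClass.NOLC_FP)
            if lc:
                dx = sub["lead_time"].to_numpy()
            elif outcome is OutcomeClass.NOLC_FP:
                dx = 1.0
            else:
                dx = None
            cell = PathwayCell(PathwayClass(pw), outcome, 1.0, dx)
            mi_cell = mi_arm.replace(u_nolc=sub["utility"].to_numpy())
            cb = cost_for_cell(cell, mi_cell, disc)
            cost[idx] = np.broadcast_to(np.asarray(cb.total, float), (len(sub),))
            qaly[idx] = np.broadcast_to(
                np.asarray(qaly_for_cell(cell, mi_cell, disc), float), (len(sub),)
            )
        rows.append(
            {
                "arm": arm,
                "strategy": arm_strategy.name,
                "n": len(grp),
                "mean_cost": float(cost.mean()),
                "mean_qaly": float(qaly.mean()),
                "se_cost": float(cost.std(ddof=1) / math.sqrt(len(grp)))
                if len(grp) > 1 else 0.0,
                "se_qaly": float(qaly.std(ddof=1) / math.sqrt(len(grp)))
                if len(grp) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def simulate_km_points(
    m: WeibullModel, n: int, censor: float, rng: np.random.Generator
) -> list[KMPoint]:
    """Kaplan–Meier estimate from ``n`` Weibull survival draws with
    administrative censoring at ``censor`` years, one point per event time."""
    if n < 10:
        raise ValueError("need at least 10 draws")
    t = m.scale * rng.weibull(m.shape, n)
    observed = t <= censor
    times = np.minimum(t, censor)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)
    sf = kmf.survival_function_
    out = [
        KMPoint(float(ti), float(si))
        for ti, si in zip(sf.index.to_numpy(), sf.iloc[:, 0].to_numpy())
        if ti > 0
    ]
    return out
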