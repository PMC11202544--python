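"""Strategy evaluation, incremental comparisons, PSA, CEAC, DSA, scenarios.

The decision tree is multilinear in its parameters, so a strategy's expected
cost and QALYs are exact closed-form sums over pathway cells; the PSA
re-evaluates those sums on vectorised parameter draws shared across
strategies (common random numbers), which makes incremental quantities
free of between-strategy Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import strategy_cost
from .outcomes import DiscountSpec, qaly_for_cell
from .parameters import (
    EvaluationSettings,
    ModelInputs,
    ParameterSet,
    StrategyConfig,
    make_strategy,
)
from .tree import pathway_distribution

__all__ = [
    "StrategyResult",
    "IncrementalResult",
    "PSAResult",
    "DSAEntry",
    "ScenarioSpec",
    "evaluate_strategy",
    "compare",
    "run_psa",
    "ceac",
    "run_dsa",
    "run_scenarios",
    "default_strategies",
    "base_case_tables",
]


def default_strategies() -> list[StrategyConfig]:
    """The three compared alternatives: blood-test triage, no screening,
    universal LDCT."""
    return [
        make_strategy("ecls"),
        make_strategy("no_screening"),
        make_strategy("full_ldct"),
    ]


@dataclass(frozen=True)
class StrategyResult:
    strategy: str
    cost: float
    qaly: float
    cost_components: dict = field(default_factory=dict)


@dataclass(frozen=True)
class IncrementalResult:
    """``reference`` minus ``comparator``; NMB per threshold."""

    reference: str
    comparator: str
    d_cost: float
    d_qaly: float
    icer: float | None
    icer_flag: str  # "" | "dominant" | "dominated" | "undefined"
    d_nmb: dict

    @classmethod
    def from_results(cls, a: StrategyResult, b: StrategyResult, thresholds):
        d_cost = a.cost - b.cost
        d_qaly = a.qaly - b.qaly
        if d_qaly == 0.0:
            icer, flag = None, "undefined"
        else:
            icer = d_cost / d_qaly
            if d_qaly > 0 and d_cost <= 0:
                flag = "dominant"
            elif d_qaly < 0 and d_cost >= 0:
                flag = "dominated"
            else:
                flag = ""
        d_nmb = {float(lam): lam * d_qaly - d_cost for lam in thresholds}
        return cls(a.strategy, b.strategy, d_cost, d_qaly, icer, flag, d_nmb)


def _cost_qaly(mi: ModelInputs, strategy: StrategyConfig,
               settings: EvaluationSettings):
    """Expected (cost, qaly) per cohort; scalar or per-draw arrays."""
    disc = DiscountSpec(settings.discount_rate, settings.discount_free_years)
    dist = pathway_distribution(mi, strategy)
    cost = strategy_cost(dist, disc, settings.cohort_size)
    qaly = 0.0
    for cell in dist.cells:
        qaly = qaly + cell.probability * qaly_for_cell(cell, dist.inputs, disc)
    return cost, qaly * settings.cohort_size


def evaluate_strategy(
    params: ParameterSet | ModelInputs,
    strategy: StrategyConfig,
    settings: EvaluationSettings | None = None,
) -> StrategyResult:
    """Deterministic expected cost and QALYs per cohort for one strategy."""
    settings = settings or EvaluationSettings()
    mi = params.base() if isinstance(params, ParameterSet) else params
    cost, qaly = _cost_qaly(mi, strategy, settings)
    return StrategyResult(
        strategy.name,
        float(cost["total"]),
        float(qaly),
        {k: float(v) for k, v in cost.items() if k != "total"},
    )


def compare(
    a: StrategyResult, b: StrategyResult, thresholds=(20000.0, 30000.0)
) -> IncrementalResult:
    """Incremental cost, QALYs, ICER and NMB of strategy ``a`` vs ``b``."""
    return IncrementalResult.from_results(a, b, thresholds)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    strategies: tuple[str, ...]
    costs: dict          # name -> per-draw cost array (per cohort)
    qalys: dict          # name -> per-draw QALY array (per cohort)
    summary: pd.DataFrame
    ceac: pd.DataFrame
    seed: int
    settings: EvaluationSettings

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.costs.values())))


def _normal_ci(x: np.ndarray) -> tuple[float, float]:
    """Normal interval on the per-draw distribution (mean +/- 1.96 SD);
    these intervals describe parameter uncertainty, not Monte Carlo error."""
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return mu - 1.96 * sd, mu + 1.96 * sd


def run_psa(
    params: ParameterSet,
    strategies: list[StrategyConfig] | None = None,
    settings: EvaluationSettings | None = None,
    seed: int | None = None,
) -> PSAResult:
    """Monte Carlo PSA with common parameter draws across strategies."""
    settings = settings or EvaluationSettings()
    strategies = strategies or default_strategies()
    seed = settings.rng_seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    mi = params.sample(rng, settings.psa_draws)

    costs: dict[str, np.ndarray] = {}
    qalys: dict[str, np.ndarray] = {}
    for strat in strategies:
        c, q = _cost_qaly(mi, strat, settings)
        costs[strat.name] = np.broadcast_to(
            np.asarray(c["total"], dtype=float), (settings.psa_draws,)
        ).copy()
        qalys[strat.name] = np.broadcast_to(
            np.asarray(q, dtype=float), (settings.psa_draws,)
        ).copy()

    rows = []
    for name in costs:
        c_lo, c_hi = _normal_ci(costs[name])
        q_lo, q_hi = _normal_ci(qalys[name])
        row = {
            "strategy": name,
            "cost_mean": float(np.mean(costs[name])),
            "cost_lo": c_lo, "cost_hi": c_hi,
            "qaly_mean": float(np.mean(qalys[name])),
            "qaly_lo": q_lo, "qaly_hi": q_hi,
        }
        for lam in settings.thresholds:
            nmb = lam * qalys[name] - costs[name]
            lo, hi = _normal_ci(nmb)
            row[f"nmb_{int(lam)}"] = float(np.mean(nmb))
            row[f"nmb_{int(lam)}_lo"] = lo
            row[f"nmb_{int(lam)}_hi"] = hi
        rows.append(row)
    summary = pd.DataFrame(rows)

    result = PSAResult(
        tuple(costs), costs, qalys, summary, pd.DataFrame(), seed, settings
    )
    ceac_table = ceac(result, settings.ceac_grid)
    return PSAResult(
        tuple(costs), costs, qalys, summary, ceac_table, seed, settings
    )


def ceac(psa: PSAResult, grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value, the fraction of draws in which each
    strategy attains the maximal net monetary benefit; exact ties (measure
    zero under continuous draws) split their count equally.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    names = list(psa.costs)
    C = np.stack([psa.costs[n] for n in names])   # (S, n)
    Q = np.stack([psa.qalys[n] for n in names])
    rows = []
    for lam in grid:
        nmb = lam * Q - C
        best = nmb.max(axis=0)
        winners = nmb == best[None, :]
        share = winners / winners.sum(axis=0, keepdims=True)
        probs = share.mean(axis=1)
        for name, pr in zip(names, probs):
            rows.append({"threshold": float(lam), "strategy": name,
                         "probability": float(pr)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis


@dataclass(frozen=True)
class DSAEntry:
    parameter: str
    setting: str           # "min" | "max"
    value: float
    results: dict          # strategy -> StrategyResult
    incrementals: dict     # comparator -> IncrementalResult (reference first)


def _evaluate_all(params: ParameterSet, strategies, settings):
    return {s.name: evaluate_strategy(params, s, settings) for s in strategies}


def _incrementals(results: dict, reference: str, thresholds) -> dict:
    ref = results[reference]
    return {
        name: compare(ref, res, thresholds)
        for name, res in results.items()
        if name != reference
    }


def run_dsa(
    params: ParameterSet,
    strategies: list[StrategyConfig] | None = None,
    settings: EvaluationSettings | None = None,
    parameters: list[str] | None = None,
) -> list[DSAEntry]:
    """One-at-a-time evaluation at the min and max of each ranged parameter.

    The discount rate is varied too (through the evaluation settings), at
    the rates conventionally used for that check.  Requesting a parameter
    without a stored range raises ``ValueError``.
    """
    settings = settings or EvaluationSettings()
    strategies = strategies or default_strategies()
    reference = strategies[0].name

    ranged = {p.name: p.dsa_range for p in params.dsa_parameters()}
    if parameters is not None:
        missing = [n for n in parameters if n not in ranged and n != "discount_rate"]
        if missing:
            raise ValueError(f"no DSA range for: {', '.join(missing)}")
        names = parameters
    else:
        names = list(ranged) + ["discount_rate"]

    entries: list[DSAEntry] = []
    for name in names:
        if name == "discount_rate":
            lo, hi = settings.discount_rate_dsa
        else:
            lo, hi = ranged[name]
        for setting, value in (("min", lo), ("max", hi)):
            if name == "discount_rate":
                mod_params = params
                mod_settings = EvaluationSettings(
                    cohort_size=settings.cohort_size,
                    discount_rate=value,
                    discount_free_years=settings.discount_free_years,
                    thresholds=settings.thresholds,
                    psa_draws=settings.psa_draws,
                    rng_seed=settings.rng_seed,
                    ceac_grid=settings.ceac_grid,
                )
            else:
                mod_params = params.with_value(name, value)
                mod_settings = settings
            results = _evaluate_all(mod_params, strategies, mod_settings)
            entries.append(
                DSAEntry(
                    name, setting, float(value), results,
                    _incrementals(results, reference, settings.thresholds),
                )
            )
    return entries


def dsa_frame(entries: list[DSAEntry]) -> pd.DataFrame:
    """DSA entries as a tidy frame (parameter x setting x strategy)."""
    rows = []
    for e in entries:
        for name, res in e.results.items():
            inc = e.incrementals.get(name)
            row = {
                "parameter": e.parameter, "setting": e.setting,
                "value": e.value, "strategy": name,
                "cost": res.cost, "qaly": res.qaly,
            }
            if inc is not None:
                row["d_cost_vs_comparator"] = -inc.d_cost
                row["d_qaly_vs_comparator"] = -inc.d_qaly
                for lam, v in inc.d_nmb.items():
                    row[f"d_nmb_{int(lam)}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    strategy: StrategyConfig


def default_scenarios() -> list[ScenarioSpec]:
    """The two policy scenarios probing the triage test's value.

    Scenario 1 halves the early-stage sensitivity to 25% (late-stage
    sensitivity, specificity and cost unchanged).  Scenario 2 is a
    zero-cost "random test": positives arise with probability 52%
    regardless of disease state, so the false-positive rate equals the
    true-positive rate.
    """
    return [
        ScenarioSpec(
            "scenario1_sens_es_25",
            StrategyConfig("scenario1_sens_es_25", sens_es_override=0.25),
        ),
        ScenarioSpec(
            "scenario2_random_test",
            StrategyConfig(
                "scenario2_random_test",
                sens_es_override=0.52,
                sens_ls_override=0.52,
                spec_override=0.48,
                test_cost_override=0.0,
            ),
        ),
    ]


def run_scenarios(
    params: ParameterSet,
    settings: EvaluationSettings | None = None,
    scenarios: list[ScenarioSpec] | None = None,
) -> pd.DataFrame:
    """Scenario and base alternatives on the incremental CE plane vs no
    screening: columns (alternative, cost, qaly, d_cost, d_qaly, icer)."""
    settings = settings or EvaluationSettings()
    scenarios = scenarios or default_scenarios()
    alts = default_strategies() + [s.strategy for s in scenarios]
    results = {s.name: evaluate_strategy(params, s, settings) for s in alts}
    ref = results["no_screening"]
    rows = []
    for name, res in results.items():
        inc = compare(res, ref, settings.thresholds)
        rows.append(
            {
                "alternative": name,
                "cost": res.cost,
                "qaly": res.qaly,
                "d_cost": inc.d_cost,
                "d_qaly": inc.d_qaly,
                "icer": inc.icer,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting frames


def base_case_tables(
    params: ParameterSet,
    strategies: list[StrategyConfig] | None = None,
    settings: EvaluationSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strategy and incremental frames mirroring the published base-case
    layout (reference strategy compared against each comparator)."""
    settings = settings or EvaluationSettings()
    strategies = strategies or default_strategies()
    results = _evaluate_all(params, strategies, settings)
    per_strategy = pd.DataFrame(
        [
            {
                "strategy": name,
                "cost": res.cost,
                "qaly": res.qaly,
                **{f"nmb_{int(lam)}": lam * res.qaly - res.cost
                   for lam in settings.thresholds},
                **{f"cost_{k}": v for k, v in res.cost_components.items()},
            }
            for name, res in results.items()
        ]
    )
    incs = _incrementals(results, strategies[0].name, settings.thresholds)
    incremental = pd.DataFrame(
        [
            {
                "reference": inc.reference,
                "comparator": name,
                "d_cost": inc.d_cost,
                "d_qaly": inc.d_qaly,
                "icer": inc.icer,
                "icer_flag": inc.icer_flag,
                **{f"d_nmb_{int(lam)}": v for lam, v in inc.d_nmb.items()},
            }
            for name, inc in incs.items()
        ]
    )
    return per_strategy, incremental
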