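"""Model parameters: definition, validation, configuration I/O and PSA sampling.

Every model input is a leaf :class:`Parameter` carrying its base value, an
optional PSA sampling distribution and an optional one-way DSA range.  The
full collection is a :class:`ParameterSet`, loadable from a YAML document;
the packaged default reproduces the published base case.

:class:`ModelInputs` is the flat numeric container consumed by the decision
tree and the cost/outcome engines.  Its fields are plain floats for a
deterministic evaluation, or equal-length numpy arrays for a vectorised PSA
(one entry per Monte Carlo draw) — all downstream arithmetic broadcasts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "Parameter",
    "ParameterSet",
    "ModelInputs",
    "StrategyConfig",
    "EvaluationSettings",
    "EpidemiologyParams",
    "ScreeningAccuracy",
    "CostParams",
    "OutcomeParams",
    "gamma_from_mean_sd",
    "load_parameters",
    "default_parameters",
    "make_strategy",
]


class ParameterError(ValueError):
    """Raised for a missing, out-of-range or malformed parameter."""


# ---------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one parameter for the PSA.

    ``kind`` is one of ``fixed``, ``beta``, ``gamma``, ``normal``.  For
    ``beta``, ``a``/``b`` are the shape parameters; for ``gamma`` they are
    shape and scale; for ``normal`` they are mean and SD.  ``derived_from``
    records the (mean, sd) pair when a gamma/normal spec was stated as
    mean +/- SD.
    """

    kind: str
    a: float = 0.0
    b: float = 0.0
    derived_from: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "beta", "gamma", "normal"):
            raise ParameterError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "beta" and not (self.a > 0 and self.b > 0):
            raise ParameterError("beta requires a>0 and b>0")
        if self.kind == "gamma" and not (self.a > 0 and self.b > 0):
            raise ParameterError("gamma requires positive shape and scale")
        if self.kind == "normal" and self.b < 0:
            raise ParameterError("normal requires sd>=0")

    def mean(self, base_value: float = 0.0) -> float:
        if self.kind == "fixed":
            return base_value
        if self.kind == "beta":
            return self.a / (self.a + self.b)
        if self.kind == "gamma":
            return self.a * self.b
        return self.a

    def sample(
        self,
        rng: np.random.Generator,
        size: int,
        base_value: float,
        nonnegative: bool = False,
    ) -> np.ndarray:
        """Draw ``size`` values.

        With ``nonnegative=True`` normal draws below zero are resampled.
        That truncation is reserved for strictly positive quantities (life
        expectancies) where the sub-zero mass — hence the induced mean
        bias — is negligible at the stated SDs.  Utility decrements are
        sampled without truncation: their sub-zero mass is not negligible,
        truncating would shift the PSA mean well away from the base value,
        and a negative draw merely means a draw above the less-decremented
        utility (the final stage utility is clamped to [0, 1] downstream).
        """
        if self.kind == "fixed":
            return np.full(size, float(base_value))
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size)
        if self.kind == "gamma":
            return rng.gamma(self.a, self.b, size)
        out = rng.normal(self.a, self.b, size)
        if nonnegative:
            for _ in range(100):
                bad = out < 0.0
                if not bad.any():
                    break
                out[bad] = rng.normal(self.a, self.b, int(bad.sum()))
            out = np.clip(out, 0.0, None)
        return out


def gamma_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Moment-matched shape-scale gamma: shape=(mean/sd)^2, scale=sd^2/mean."""
    if not (mean > 0 and sd > 0):
        raise ParameterError("gamma_from_mean_sd requires mean>0 and sd>0")
    return DistributionSpec(
        "gamma", (mean / sd) ** 2, sd**2 / mean, derived_from=(mean, sd)
    )


# ---------------------------------------------------------------------------
# schema

# (group, key, bound) — bound: "prob" in [0,1], "nonneg" >= 0, "pos" > 0
_SCHEMA: tuple[tuple[str, str, str], ...] = (
    ("epidemiology", "prevalence", "prob"),
    ("epidemiology", "prevalence_early", "prob"),
    ("epidemiology", "op_es", "prob"),
    ("epidemiology", "op_ls", "prob"),
    ("accuracy", "sens_es", "prob"),
    ("accuracy", "sens_ls", "prob"),
    ("accuracy", "spec", "prob"),
    ("accuracy", "ldct_sens", "prob"),
    ("accuracy", "ldct_spec", "prob"),
    ("costs", "test_cost", "nonneg"),
    ("costs", "diag_tp_fp", "nonneg"),
    ("costs", "diag_tp_noldct", "nonneg"),
    ("costs", "diag_tn_fn_ldct", "nonneg"),
    ("costs", "treat_es", "nonneg"),
    ("costs", "treat_ls", "nonneg"),
    ("costs", "prop_fn_treated", "prob"),
    ("costs", "prop_es_recur", "prob"),
    ("outcomes", "leadtime_es", "pos"),
    ("outcomes", "leadtime_ls", "pos"),
    ("outcomes", "le_stage_i", "pos"),
    ("outcomes", "le_stage_ii", "pos"),
    ("outcomes", "le_stage_iii_prior", "pos"),
    ("outcomes", "le_stage_iv_prior", "pos"),
    ("outcomes", "le_stage_iii_immuno", "pos"),
    ("outcomes", "le_stage_iv_immuno", "pos"),
    ("outcomes", "hr_immuno", "pos"),
    ("outcomes", "u_nolc", "prob"),
    ("outcomes", "u_dec_lc", "nonneg"),
    ("outcomes", "u_dec_es", "nonneg"),
    ("outcomes", "u_dec_ls", "nonneg"),
    ("outcomes", "utility_decrement_years", "pos"),
    ("outcomes", "baseline_disc_qaly_nolc", "nonneg"),
)

_GROUPS = tuple(dict.fromkeys(g for g, _, _ in _SCHEMA))
_KEY_TO_GROUP = {k: g for g, k, _ in _SCHEMA}
_KEY_BOUND = {k: b for _, k, b in _SCHEMA}


def _check_bound(key: str, value: float) -> None:
    bound = _KEY_BOUND[key]
    if bound == "prob" and not (0.0 <= value <= 1.0):
        raise ParameterError(f"{key}={value} outside [0, 1]")
    if bound == "nonneg" and value < 0.0:
        raise ParameterError(f"{key}={value} must be >= 0")
    if bound == "pos" and value <= 0.0:
        raise ParameterError(f"{key}={value} must be > 0")


@dataclass(frozen=True)
class Parameter:
    """One model input: base value, PSA distribution and optional DSA range."""

    name: str
    value: float
    dist: DistributionSpec = field(default_factory=lambda: DistributionSpec("fixed"))
    dsa_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        _check_bound(self.name, self.value)
        if self.dsa_range is not None:
            lo, hi = self.dsa_range
            if lo > hi:
                raise ParameterError(f"{self.name}: DSA range min {lo} > max {hi}")


# ---------------------------------------------------------------------------
# flat numeric container


@dataclass(frozen=True)
class ModelInputs:
    """One numeric realisation of every model input.

    Fields are floats (deterministic) or broadcastable numpy arrays (one
    entry per PSA draw).
    """

    prevalence: float | np.ndarray
    prevalence_early: float | np.ndarray
    op_es: float | np.ndarray
    op_ls: float | np.ndarray
    sens_es: float | np.ndarray
    sens_ls: float | np.ndarray
    spec: float | np.ndarray
    ldct_sens: float | np.ndarray
    ldct_spec: float | np.ndarray
    test_cost: float | np.ndarray
    diag_tp_fp: float | np.ndarray
    diag_tp_noldct: float | np.ndarray
    diag_tn_fn_ldct: float | np.ndarray
    treat_es: float | np.ndarray
    treat_ls: float | np.ndarray
    prop_fn_treated: float | np.ndarray
    prop_es_recur: float | np.ndarray
    leadtime_es: float | np.ndarray
    leadtime_ls: float | np.ndarray
    le_stage_i: float | np.ndarray
    le_stage_ii: float | np.ndarray
    le_stage_iii_prior: float | np.ndarray
    le_stage_iv_prior: float | np.ndarray
    le_stage_iii_immuno: float | np.ndarray
    le_stage_iv_immuno: float | np.ndarray
    hr_immuno: float | np.ndarray
    u_nolc: float | np.ndarray
    u_dec_lc: float | np.ndarray
    u_dec_es: float | np.ndarray
    u_dec_ls: float | np.ndarray
    utility_decrement_years: float | np.ndarray
    baseline_disc_qaly_nolc: float | np.ndarray

    def replace(self, **changes: float | np.ndarray) -> "ModelInputs":
        return dataclasses.replace(self, **changes)


# typed read-only views -----------------------------------------------------


@dataclass(frozen=True)
class EpidemiologyParams:
    p: float
    p_es: float
    op_es: float
    op_ls: float

    @property
    def p_ls(self) -> float:
        return 1.0 - self.p_es


@dataclass(frozen=True)
class ScreeningAccuracy:
    sens_es: float
    sens_ls: float
    spec: float
    ldct_sens: float
    ldct_spec: float


@dataclass(frozen=True)
class CostParams:
    test_cost: float
    diag_tp_fp: float
    diag_tp_noldct: float
    diag_tn_fn_ldct: float
    diag_negative: float
    treat_es: float
    treat_ls: float
    prop_fn_treated: float
    prop_es_recur: float


@dataclass(frozen=True)
class OutcomeParams:
    leadtime_es: float
    leadtime_ls: float
    le_stage: dict
    hr_immuno: float
    u_nolc: float
    u_dec_lc: float
    u_dec_es: float
    u_dec_ls: float
    utility_decrement_years: float
    baseline_disc_qaly_nolc: float


# ---------------------------------------------------------------------------
# parameter set


class ParameterSet:
    """All model parameters keyed by name, in a fixed schema order."""

    def __init__(self, params: dict[str, Parameter]):
        missing = [k for _, k, _ in _SCHEMA if k not in params]
        if missing:
            raise ParameterError(f"missing parameter(s): {', '.join(missing)}")
        unknown = [k for k in params if k not in _KEY_TO_GROUP]
        if unknown:
            raise ParameterError(f"unknown parameter(s): {', '.join(unknown)}")
        self._params = {k: params[k] for _, k, _ in _SCHEMA}

    def __getitem__(self, key: str) -> Parameter:
        return self._params[key]

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self._params.values())

    def with_value(self, key: str, value: float) -> "ParameterSet":
        """Copy with one base value replaced (used by the DSA)."""
        if key not in self._params:
            raise ParameterError(f"unknown parameter {key!r}")
        params = dict(self._params)
        params[key] = dataclasses.replace(params[key], value=float(value))
        return ParameterSet(params)

    # construction -----------------------------------------------------

    @classmethod
    def from_yaml_text(cls, text: str) -> "ParameterSet":
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ParameterError("configuration must be a mapping of groups")
        unknown_groups = set(doc) - set(_GROUPS)
        if unknown_groups:
            raise ParameterError(
                f"unknown group(s): {', '.join(sorted(unknown_groups))}"
            )
        params: dict[str, Parameter] = {}
        for group in _GROUPS:
            entries = doc.get(group, {}) or {}
            if not isinstance(entries, dict):
                raise ParameterError(f"group {group!r} must be a mapping")
            for key, node in entries.items():
                if key not in _KEY_TO_GROUP or _KEY_TO_GROUP[key] != group:
                    raise ParameterError(f"unknown key {key!r} in group {group!r}")
                params[key] = _parse_leaf(key, node)
        return cls(params)

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_yaml_text(fh.read())

    @classmethod
    def default(cls) -> "ParameterSet":
        text = (
            resources.files("lungscreen.data")
            .joinpath("default_parameters.yaml")
            .read_text(encoding="utf-8")
        )
        return cls.from_yaml_text(text)

    def to_yaml_text(self) -> str:
        doc: dict[str, dict] = {g: {} for g in _GROUPS}
        for par in self:
            doc[_KEY_TO_GROUP[par.name]][par.name] = _leaf_to_node(par)
        return yaml.safe_dump(doc, sort_keys=False)

    # realisations -----------------------------------------------------

    def base(self) -> ModelInputs:
        """Deterministic realisation at the base values."""
        return ModelInputs(**{p.name: p.value for p in self})

    def sample(self, rng: np.random.Generator, size: int) -> ModelInputs:
        """One joint independent PSA draw of length ``size`` per parameter.

        Parameters without a stated distribution stay at their base value
        in every draw.  Sampling order follows the schema, so a given seed
        reproduces the same realisation across runs.
        """
        values: dict[str, np.ndarray] = {}
        for par in self:
            values[par.name] = par.dist.sample(
                rng, size, par.value, nonnegative=_KEY_BOUND[par.name] == "pos"
            )
        return ModelInputs(**values)

    def dsa_parameters(self) -> list[Parameter]:
        return [p for p in self if p.dsa_range is not None]

    def distribution_divergences(self, rel_tol: float = 0.01) -> list[str]:
        """Names of parameters whose PSA-distribution mean strays from the
        base value by more than ``rel_tol`` (reported, never auto-corrected)."""
        out = []
        for par in self:
            if par.dist.kind == "fixed":
                continue
            m = par.dist.mean(par.value)
            ref = abs(par.value) if par.value != 0 else 1.0
            if abs(m - par.value) / ref > rel_tol:
                out.append(par.name)
        return out

    # typed views ------------------------------------------------------

    @property
    def epi(self) -> EpidemiologyParams:
        g = self._params
        return EpidemiologyParams(
            g["prevalence"].value,
            g["prevalence_early"].value,
            g["op_es"].value,
            g["op_ls"].value,
        )

    @property
    def accuracy(self) -> ScreeningAccuracy:
        g = self._params
        return ScreeningAccuracy(
            g["sens_es"].value,
            g["sens_ls"].value,
            g["spec"].value,
            g["ldct_sens"].value,
            g["ldct_spec"].value,
        )

    @property
    def costs(self) -> CostParams:
        g = self._params
        return CostParams(
            g["test_cost"].value,
            g["diag_tp_fp"].value,
            g["diag_tp_noldct"].value,
            g["diag_tn_fn_ldct"].value,
            0.0,
            g["treat_es"].value,
            g["treat_ls"].value,
            g["prop_fn_treated"].value,
            g["prop_es_recur"].value,
        )

    @property
    def outcomes(self) -> OutcomeParams:
        g = self._params
        return OutcomeParams(
            g["leadtime_es"].value,
            g["leadtime_ls"].value,
            {
                "I": g["le_stage_i"].value,
                "II": g["le_stage_ii"].value,
                "III_prior": g["le_stage_iii_prior"].value,
                "IV_prior": g["le_stage_iv_prior"].value,
                "III_immuno": g["le_stage_iii_immuno"].value,
                "IV_immuno": g["le_stage_iv_immuno"].value,
            },
            g["hr_immuno"].value,
            g["u_nolc"].value,
            g["u_dec_lc"].value,
            g["u_dec_es"].value,
            g["u_dec_ls"].value,
            g["utility_decrement_years"].value,
            g["baseline_disc_qaly_nolc"].value,
        )


def _parse_leaf(key: str, node) -> Parameter:
    if isinstance(node, (int, float)):
        node = {"value": float(node)}
    if not isinstance(node, dict):
        raise ParameterError(f"{key}: expected a mapping or number")
    extra = set(node) - {"value", "psa", "dsa"}
    if extra:
        raise ParameterError(f"{key}: unknown field(s) {', '.join(sorted(extra))}")
    if "value" not in node:
        raise ParameterError(f"{key}: missing 'value'")
    try:
        value = float(node["value"])
    except (TypeError, ValueError):
        raise ParameterError(f"{key}: value {node['value']!r} is not a number")
    dist = DistributionSpec("fixed")
    if "psa" in node and node["psa"] is not None:
        psa = node["psa"]
        if not isinstance(psa, dict) or "dist" not in psa:
            raise ParameterError(f"{key}: malformed psa spec {psa!r}")
        kind = psa["dist"]
        try:
            if kind == "beta":
                dist = DistributionSpec("beta", float(psa["a"]), float(psa["b"]))
            elif kind == "gamma":
                dist = gamma_from_mean_sd(value, float(psa["sd"]))
            elif kind == "normal":
                dist = DistributionSpec("normal", value, float(psa["sd"]))
            else:
                raise ParameterError(f"{key}: unknown psa distribution {kind!r}")
        except KeyError as exc:
            raise ParameterError(f"{key}: psa spec missing {exc}")
    dsa = None
    if "dsa" in node and node["dsa"] is not None:
        rng = node["dsa"]
        if not (isinstance(rng, (list, tuple)) and len(rng) == 2):
            raise ParameterError(f"{key}: dsa must be [min, max]")
        dsa = (float(rng[0]), float(rng[1]))
    try:
        return Parameter(key, value, dist, dsa)
    except ParameterError as exc:
        raise ParameterError(str(exc))


def _leaf_to_node(par: Parameter) -> dict:
    node: dict = {"value": par.value}
    d = par.dist
    if d.kind == "beta":
        node["psa"] = {"dist": "beta", "a": d.a, "b": d.b}
    elif d.kind in ("gamma", "normal"):
        sd = d.derived_from[1] if d.derived_from else d.b
        node["psa"] = {"dist": d.kind, "sd": sd}
    if par.dsa_range is not None:
        node["dsa"] = list(par.dsa_range)
    return node


def load_parameters(config_text: str) -> ParameterSet:
    """Parse and validate a YAML parameter document (see the packaged
    ``default_parameters.yaml`` for the expected layout)."""
    return ParameterSet.from_yaml_text(config_text)


def default_parameters() -> ParameterSet:
    """The packaged base-case parameter set."""
    return ParameterSet.default()


# ---------------------------------------------------------------------------
# strategies and settings


@dataclass(frozen=True)
class StrategyConfig:
    """A screening strategy as overrides of the triage-test accuracy and cost.

    ``None`` means "use the parameter set's value" (the blood-test values).
    """

    name: str
    sens_es_override: float | None = None
    sens_ls_override: float | None = None
    spec_override: float | None = None
    test_cost_override: float | None = None

    def __post_init__(self) -> None:
        for attr in ("sens_es_override", "sens_ls_override", "spec_override"):
            v = getattr(self, attr)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ParameterError(f"{self.name}: {attr}={v} outside [0, 1]")
        if self.test_cost_override is not None and self.test_cost_override < 0:
            raise ParameterError(f"{self.name}: negative test cost")


def make_strategy(kind: str, **overrides) -> StrategyConfig:
    """Construct one of the canonical strategies, or a custom variant.

    ``ecls``
        blood-test triage at the trial-estimated accuracy and test cost;
    ``no_screening``
        a free test with sensitivity 0 and specificity 1 (nobody is sent
        to LDCT);
    ``full_ldct``
        a free test with sensitivity 1 and specificity 0 (everybody is
        sent to LDCT);
    ``custom``
        explicit overrides via keyword arguments.
    """
    if kind == "ecls":
        return StrategyConfig("ecls", **overrides)
    if kind == "no_screening":
        return StrategyConfig(
            "no_screening",
            sens_es_override=0.0,
            sens_ls_override=0.0,
            spec_override=1.0,
            test_cost_override=0.0,
        )
    if kind == "full_ldct":
        return StrategyConfig(
            "full_ldct",
            sens_es_override=1.0,
            sens_ls_override=1.0,
            spec_override=0.0,
            test_cost_override=0.0,
        )
    if kind == "custom":
        return StrategyConfig(**overrides)
    raise ParameterError(f"unknown strategy kind {kind!r}")


def apply_strategy(mi: ModelInputs, strategy: StrategyConfig) -> ModelInputs:
    """Replace triage-test accuracy and cost with the strategy's overrides."""
    changes: dict[str, float] = {}
    if strategy.sens_es_override is not None:
        changes["sens_es"] = strategy.sens_es_override
    if strategy.sens_ls_override is not None:
        changes["sens_ls"] = strategy.sens_ls_override
    if strategy.spec_override is not None:
        changes["spec"] = strategy.spec_override
    if strategy.test_cost_override is not None:
        changes["test_cost"] = strategy.test_cost_override
    return mi.replace(**changes) if changes else mi


@dataclass(frozen=True)
class EvaluationSettings:
    """Cohort size, discounting, thresholds and PSA controls."""

    cohort_size: float = 1000.0
    discount_rate: float = 0.035
    discount_free_years: float = 1.0
    thresholds: tuple[float, ...] = (20000.0, 30000.0)
    psa_draws: int = 10000
    rng_seed: int = 0
    ceac_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 50001, 1000))
    discount_rate_dsa: tuple[float, float] = (0.0, 0.06)

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ParameterError("cohort_size must be > 0")
        if self.discount_rate < 0:
            raise ParameterError("discount_rate must be >= 0")
        if self.psa_draws < 1:
            raise ParameterError("psa_draws must be >= 1")
        if len(self.ceac_grid) == 0:
            raise ParameterError("ceac_grid must be nonempty")
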