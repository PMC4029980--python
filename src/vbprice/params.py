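"""Parameter types and closed-form conversions for the cost-utility model.

Every uncertain model input is a :class:`DistributionSpec` — a small tagged
union over the four parametric families used in health-economic probabilistic
sensitivity analysis: beta for probabilities and utilities, gamma (shape/rate,
fitted by the method of moments) for right-skewed costs, uniform for a drug
acquisition price with a fixed administrative spread, and a degenerate point
mass for anything treated as known.

The module also houses the standard epidemiological conversions between
median time-to-event, event rates and per-cycle probabilities, the
discounting rule, and the GDP-multiple willingness-to-pay convention.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "ConfigError",
    "DistributionSpec",
    "TransitionProbabilities",
    "ArmSpec",
    "ModelConfig",
    "TrialSummary",
    "monthly_risk_from_median",
    "rate_from_median",
    "prob_from_rate",
    "gamma_from_moments",
    "beta_from_mean_se",
    "beta_from_counts",
    "wtp_from_gdp",
    "cycle_discount_factor",
    "load_config",
    "dump_config",
    "load_reference_config",
]


class ParameterError(ValueError):
    """A scalar parameter violates its mathematical precondition."""


class ConfigError(ValueError):
    """A model configuration failed validation.

    Carries ``issues``: a list of ``(field_path, message)`` pairs naming each
    offending field.
    """

    def __init__(self, issues: Sequence[tuple[str, str]]):
        self.issues = list(issues)
        lines = "; ".join(f"{f}: {m}" for f, m in self.issues)
        super().__init__(f"invalid model configuration: {lines}")


# ---------------------------------------------------------------------------
# Distribution specifications
# ---------------------------------------------------------------------------

_KINDS = ("beta", "gamma", "uniform", "point")


@dataclass(frozen=True)
class DistributionSpec:
    """A tagged parametric distribution for one uncertain model input.

    kind/params pairs:
      * ``beta``    — (alpha, beta), support (0, 1)
      * ``gamma``   — (shape, rate), support (0, inf); mean = shape/rate
      * ``uniform`` — (lower, upper)
      * ``point``   — (value,), a degenerate point mass
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown distribution kind {self.kind!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        p = self.params
        if self.kind == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ParameterError(f"beta requires alpha > 0, beta > 0, got {p}")
        elif self.kind == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ParameterError(f"gamma requires shape > 0, rate > 0, got {p}")
        elif self.kind == "uniform":
            if len(p) != 2 or p[0] > p[1]:
                raise ParameterError(f"uniform requires lower <= upper, got {p}")
        elif self.kind == "point":
            if len(p) != 1:
                raise ParameterError(f"point requires a single value, got {p}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def beta(cls, alpha: float, beta: float) -> "DistributionSpec":
        return cls("beta", (alpha, beta))

    @classmethod
    def gamma(cls, shape: float, rate: float) -> "DistributionSpec":
        return cls("gamma", (shape, rate))

    @classmethod
    def uniform(cls, lower: float, upper: float) -> "DistributionSpec":
        return cls("uniform", (lower, upper))

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", (value,))

    # -- moments and sampling ----------------------------------------------

    def mean(self) -> float:
        a = self.params
        if self.kind == "beta":
            return a[0] / (a[0] + a[1])
        if self.kind == "gamma":
            return a[0] / a[1]
        if self.kind == "uniform":
            return 0.5 * (a[0] + a[1])
        return a[0]

    def variance(self) -> float:
        a = self.params
        if self.kind == "beta":
            s = a[0] + a[1]
            return a[0] * a[1] / (s * s * (s + 1.0))
        if self.kind == "gamma":
            return a[0] / (a[1] * a[1])
        if self.kind == "uniform":
            return (a[1] - a[0]) ** 2 / 12.0
        return 0.0

    def sd(self) -> float:
        return math.sqrt(self.variance())

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the distribution with the supplied generator."""
        a = self.params
        if self.kind == "beta":
            return rng.beta(a[0], a[1], size=size)
        if self.kind == "gamma":
            return rng.gamma(a[0], 1.0 / a[1], size=size)
        if self.kind == "uniform":
            return rng.uniform(a[0], a[1], size=size)
        if size is None:
            return a[0]
        return np.full(size, a[0])


# ---------------------------------------------------------------------------
# Closed-form conversions
# ---------------------------------------------------------------------------


def monthly_risk_from_median(median_months: float) -> float:
    """Per-month event risk implied by a median time-to-event.

    Under a constant hazard, the probability of the event within one month is
    ``1 - 0.5**(1/median)``: half the cohort has had the event by the median,
    so the monthly survival fraction is ``0.5**(1/median)``.
    """
    if median_months <= 0:
        raise ParameterError(f"median must be positive, got {median_months}")
    return 1.0 - 0.5 ** (1.0 / median_months)


def rate_from_median(median_months: float, n_cycles: int = 1) -> float:
    """Constant event rate (per cycle) from a median time-to-event.

    ``R = -ln(0.5) / (median / n_cycles)``; with ``n_cycles=1`` this is the
    familiar ``ln(2)/median`` per month.
    """
    if median_months <= 0:
        raise ParameterError(f"median must be positive, got {median_months}")
    if n_cycles < 1:
        raise ParameterError(f"n_cycles must be >= 1, got {n_cycles}")
    return math.log(2.0) / (median_months / n_cycles)


def prob_from_rate(rate: float) -> float:
    """Per-cycle probability from a constant per-cycle rate: ``1 - exp(-R)``."""
    if rate < 0:
        raise ParameterError(f"rate must be non-negative, got {rate}")
    return 1.0 - math.exp(-rate)


def gamma_from_moments(mean: float, variance: float) -> DistributionSpec:
    """Fit a gamma(shape, rate) to a cost mean and variance by moments.

    shape = mean^2 / variance, rate = mean / variance.
    """
    if mean <= 0 or variance <= 0:
        raise ParameterError(
            f"gamma moment fit requires mean > 0 and variance > 0, got ({mean}, {variance})"
        )
    return DistributionSpec.gamma(mean * mean / variance, mean / variance)


def beta_from_mean_se(mean: float, se: float) -> DistributionSpec:
    """Fit a beta(alpha, beta) to a utility mean and standard error by moments.

    With ``nu = mean(1-mean)/se^2 - 1``: alpha = mean*nu, beta = (1-mean)*nu.
    The SE must be small enough for the (0,1) support, i.e.
    ``se^2 < mean(1-mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"mean must lie in (0,1), got {mean}")
    if se <= 0 or se * se >= mean * (1.0 - mean):
        raise ParameterError(
            f"se^2 must lie in (0, mean(1-mean)), got se={se} for mean={mean}"
        )
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return DistributionSpec.beta(mean * nu, (1.0 - mean) * nu)


def beta_from_counts(events: float, n: float) -> DistributionSpec:
    """Beta(alpha, beta) from transition counts: alpha = events, beta = n - events.

    ``events`` may be a non-integer pseudo-count (e.g. a printed probability
    times a sample size) as long as ``0 < events < n``.
    """
    if not 0 < events < n:
        raise ParameterError(f"require 0 < events < n, got events={events}, n={n}")
    return DistributionSpec.beta(float(events), float(n - events))


def wtp_from_gdp(
    gdp_per_capita: float, multiplier: int, rounding: Optional[float] = 10_000.0
) -> float:
    """Willingness-to-pay threshold as a multiple of GDP per capita.

    The WHO convention uses 1–3× GDP per capita per QALY; the result is
    rounded to the nearest ``rounding`` euro (pass ``None`` to disable).
    """
    if gdp_per_capita <= 0:
        raise ParameterError(f"GDP per capita must be positive, got {gdp_per_capita}")
    if multiplier not in (1, 2, 3):
        raise ParameterError(f"multiplier must be 1, 2 or 3, got {multiplier}")
    wtp = gdp_per_capita * multiplier
    if rounding:
        wtp = round(wtp / rounding) * rounding
    return float(wtp)


def cycle_discount_factor(
    annual_rate: float, cycle_index: int, cycles_per_year: int = 12
) -> float:
    """Discount factor for accrual in cycle ``t``: ``(1+r)^(-t/cycles_per_year)``.

    The annual rate is compounded at fractional-year exponents, so cycle 12 of
    a monthly model is discounted by exactly ``1/(1+r)``.
    """
    if annual_rate < 0:
        raise ParameterError(f"annual rate must be non-negative, got {annual_rate}")
    if cycle_index < 0:
        raise ParameterError(f"cycle index must be non-negative, got {cycle_index}")
    return (1.0 + annual_rate) ** (-cycle_index / cycles_per_year)


# ---------------------------------------------------------------------------
# Model configuration types
# ---------------------------------------------------------------------------

ProbLike = Union[float, DistributionSpec]


def _point_of(p: ProbLike) -> float:
    return p.mean() if isinstance(p, DistributionSpec) else float(p)


@dataclass(frozen=True)
class TransitionProbabilities:
    """Monthly transition probabilities out of the two alive disease states.

    Each field is either a fixed probability or a DistributionSpec (beta in
    practice) whose mean is the base-case value.
    """

    p_pfs_to_pd: ProbLike
    p_pfs_to_death: ProbLike
    p_pd_to_death: ProbLike

    def point(self) -> tuple[float, float, float]:
        """Base-case (mean) values of the three probabilities."""
        return (
            _point_of(self.p_pfs_to_pd),
            _point_of(self.p_pfs_to_death),
            _point_of(self.p_pd_to_death),
        )

    def issues(self, prefix: str = "transitions") -> list[tuple[str, str]]:
        out = []
        names = ("p_pfs_to_pd", "p_pfs_to_death", "p_pd_to_death")
        for name, v in zip(names, self.point()):
            if not 0.0 <= v <= 1.0:
                out.append((f"{prefix}.{name}", f"mean value {v} outside [0, 1]"))
        p_pd, p_d, _ = self.point()
        if p_pd + p_d > 1.0:
            out.append(
                (f"{prefix}", f"PFS exit probabilities sum to {p_pd + p_d} > 1")
            )
        return out


@dataclass(frozen=True)
class ArmSpec:
    """One treatment strategy: transitions plus state-dependent monthly costs.

    ``cost_pd_early_monthly`` applies during the first two months after
    progression, ``cost_pd_late_monthly`` thereafter. ``drug_cost_monthly``,
    when present, is the acquisition price handle the value-based-pricing
    solver varies; it accrues only while progression-free.
    """

    name: str
    transitions: TransitionProbabilities
    cost_pfs_monthly: DistributionSpec
    cost_pd_early_monthly: DistributionSpec
    cost_pd_late_monthly: DistributionSpec
    drug_cost_monthly: Optional[DistributionSpec] = None

    def issues(self, prefix: str = "arm") -> list[tuple[str, str]]:
        out = self.transitions.issues(f"{prefix}.transitions")
        for fname in (
            "cost_pfs_monthly",
            "cost_pd_early_monthly",
            "cost_pd_late_monthly",
            "drug_cost_monthly",
        ):
            spec = getattr(self, fname)
            if spec is None:
                continue
            if spec.mean() < 0:
                out.append((f"{prefix}.{fname}", f"mean cost {spec.mean()} < 0"))
        return out


@dataclass(frozen=True)
class TrialSummary:
    """Trial-level metadata the transition probabilities descend from.

    Stored for provenance and for the synthetic generator; the cohort model
    itself consumes only monthly probabilities.
    """

    n_intervention: int
    n_comparator: int
    median_pfs_intervention: float
    median_pfs_comparator: float
    median_os_intervention: float
    median_os_comparator: float
    hr_pfs: Optional[tuple[float, float, float]] = None  # (value, lo, hi)
    hr_os: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        for name in (
            "median_pfs_intervention",
            "median_pfs_comparator",
            "median_os_intervention",
            "median_os_comparator",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_intervention <= 0 or self.n_comparator <= 0:
            raise ParameterError("per-arm sample sizes must be positive")


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to run the cohort model and its PSA."""

    intervention: ArmSpec
    comparator: ArmSpec
    utility_pfs: DistributionSpec
    utility_pd: DistributionSpec
    cycle_length_months: float = 1.0
    horizon_cycles: int = 120
    cohort_size: float = 1000.0
    discount_annual: float = 0.035
    wtp_thresholds: tuple[float, ...] = (20_000.0, 40_000.0, 60_000.0)
    psa_iterations: int = 50_000
    seed: int = 0
    name: str = "model"
    trial: Optional[TrialSummary] = None
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def cycles_per_year(self) -> int:
        return int(round(12.0 / self.cycle_length_months))

    def arms(self) -> tuple[ArmSpec, ArmSpec]:
        return (self.intervention, self.comparator)

    def issues(self) -> list[tuple[str, str]]:
        out = []
        out += self.intervention.issues("intervention")
        out += self.comparator.issues("comparator")
        if self.horizon_cycles < 1:
            out.append(("horizon_cycles", f"must be >= 1, got {self.horizon_cycles}"))
        if self.cohort_size < 1:
            out.append(("cohort_size", f"must be >= 1, got {self.cohort_size}"))
        if not 0.0 <= self.discount_annual < 1.0:
            out.append(
                ("discount_annual", f"must lie in [0, 1), got {self.discount_annual}")
            )
        for uname in ("utility_pfs", "utility_pd"):
            u = getattr(self, uname)
            if u.kind == "point" and not 0.0 <= u.params[0] <= 1.0:
                out.append((uname, f"utility {u.params[0]} outside [0, 1]"))
            elif u.kind == "uniform" and (u.params[0] < 0 or u.params[1] > 1):
                out.append((uname, "utility support outside [0, 1]"))
            elif u.kind == "gamma":
                out.append((uname, "gamma support is unbounded above; not a utility"))
        if self.psa_iterations < 1:
            out.append(("psa_iterations", f"must be >= 1, got {self.psa_iterations}"))
        return out

    def validate(self) -> "ModelConfig":
        issues = self.issues()
        if issues:
            raise ConfigError(issues)
        return self


# ---------------------------------------------------------------------------
# YAML serialisation
# ---------------------------------------------------------------------------


def _dist_to_yaml(spec: Optional[DistributionSpec]):
    if spec is None:
        return None
    return {"dist": spec.kind, "params": list(spec.params)}


def _dist_from_yaml(node) -> DistributionSpec:
    if isinstance(node, (int, float)):
        return DistributionSpec.point(float(node))
    if "dist" not in node:
        raise ConfigError([("distribution", f"missing 'dist' key in {node!r}")])
    return DistributionSpec(str(node["dist"]), tuple(node["params"]))


def _prob_from_yaml(node) -> ProbLike:
    """A transition entry: a bare number, a {mean, n} beta recipe, or a dist."""
    if isinstance(node, (int, float)):
        return float(node)
    if "mean" in node and "n" in node:
        return beta_from_counts(float(node["mean"]) * float(node["n"]), float(node["n"]))
    return _dist_from_yaml(node)


def _prob_to_yaml(p: ProbLike):
    if isinstance(p, DistributionSpec):
        return _dist_to_yaml(p)
    return float(p)


def _arm_from_yaml(node) -> ArmSpec:
    tr = node["transitions"]
    costs = node["costs"]
    drug = costs.get("drug_monthly")
    return ArmSpec(
        name=str(node["name"]),
        transitions=TransitionProbabilities(
            p_pfs_to_pd=_prob_from_yaml(tr["pfs_to_pd"]),
            p_pfs_to_death=_prob_from_yaml(tr["pfs_to_death"]),
            p_pd_to_death=_prob_from_yaml(tr["pd_to_death"]),
        ),
        cost_pfs_monthly=_dist_from_yaml(costs["pfs_monthly"]),
        cost_pd_early_monthly=_dist_from_yaml(costs["pd_early_monthly"]),
        cost_pd_late_monthly=_dist_from_yaml(costs["pd_late_monthly"]),
        drug_cost_monthly=None if drug is None else _dist_from_yaml(drug),
    )


def _arm_to_yaml(arm: ArmSpec) -> dict:
    tr = arm.transitions
    out = {
        "name": arm.name,
        "transitions": {
            "pfs_to_pd": _prob_to_yaml(tr.p_pfs_to_pd),
            "pfs_to_death": _prob_to_yaml(tr.p_pfs_to_death),
            "pd_to_death": _prob_to_yaml(tr.p_pd_to_death),
        },
        "costs": {
            "pfs_monthly": _dist_to_yaml(arm.cost_pfs_monthly),
            "pd_early_monthly": _dist_to_yaml(arm.cost_pd_early_monthly),
            "pd_late_monthly": _dist_to_yaml(arm.cost_pd_late_monthly),
        },
    }
    if arm.drug_cost_monthly is not None:
        out["costs"]["drug_monthly"] = _dist_to_yaml(arm.drug_cost_monthly)
    return out


def _normalise_number(v):
    """Accept decimal-comma strings ('0,1605') as numbers at load time."""
    if isinstance(v, str):
        return float(v.replace(",", "."))
    return v


def _trial_from_yaml(node) -> TrialSummary:
    def _hr(key):
        h = node.get(key)
        return None if h is None else (float(h[0]), float(h[1]), float(h[2]))

    return TrialSummary(
        n_intervention=int(node["n_intervention"]),
        n_comparator=int(node["n_comparator"]),
        median_pfs_intervention=float(node["median_pfs_intervention"]),
        median_pfs_comparator=float(node["median_pfs_comparator"]),
        median_os_intervention=float(node["median_os_intervention"]),
        median_os_comparator=float(node["median_os_comparator"]),
        hr_pfs=_hr("hr_pfs"),
        hr_os=_hr("hr_os"),
    )


def config_from_dict(doc: dict) -> ModelConfig:
    """Build and validate a ModelConfig from a parsed YAML/JSON document."""
    arms = {str(a.get("role", a["name"])): a for a in doc["arms"]}
    if "intervention" not in arms or "comparator" not in arms:
        raise ConfigError(
            [("arms", "need one arm with role 'intervention' and one 'comparator'")]
        )
    cfg = ModelConfig(
        intervention=_arm_from_yaml(arms["intervention"]),
        comparator=_arm_from_yaml(arms["comparator"]),
        utility_pfs=_dist_from_yaml(doc["utilities"]["pfs"]),
        utility_pd=_dist_from_yaml(doc["utilities"]["pd"]),
        cycle_length_months=float(_normalise_number(doc.get("cycle_length_months", 1))),
        horizon_cycles=int(doc.get("horizon_cycles", 120)),
        cohort_size=float(doc.get("cohort_size", 1000)),
        discount_annual=float(_normalise_number(doc.get("discount_annual", 0.035))),
        wtp_thresholds=tuple(
            float(_normalise_number(w)) for w in doc.get("wtp_thresholds", [])
        ),
        psa_iterations=int(doc.get("psa", {}).get("iterations", 50_000)),
        seed=int(doc.get("psa", {}).get("seed", 0)),
        name=str(doc.get("name", "model")),
        trial=_trial_from_yaml(doc["trial"]) if "trial" in doc else None,
        provenance=dict(doc.get("provenance", {})),
    )
    return cfg.validate()


def config_to_dict(cfg: ModelConfig) -> dict:
    doc = {
        "name": cfg.name,
        "cycle_length_months": cfg.cycle_length_months,
        "horizon_cycles": cfg.horizon_cycles,
        "cohort_size": cfg.cohort_size,
        "discount_annual": cfg.discount_annual,
        "wtp_thresholds": list(cfg.wtp_thresholds),
        "psa": {"iterations": cfg.psa_iterations, "seed": cfg.seed},
        "utilities": {
            "pfs": _dist_to_yaml(cfg.utility_pfs),
            "pd": _dist_to_yaml(cfg.utility_pd),
        },
        "arms": [
            {**_arm_to_yaml(cfg.intervention), "role": "intervention"},
            {**_arm_to_yaml(cfg.comparator), "role": "comparator"},
        ],
    }
    if cfg.trial is not None:
        t = cfg.trial
        doc["trial"] = {
            "n_intervention": t.n_intervention,
            "n_comparator": t.n_comparator,
            "median_pfs_intervention": t.median_pfs_intervention,
            "median_pfs_comparator": t.median_pfs_comparator,
            "median_os_intervention": t.median_os_intervention,
            "median_os_comparator": t.median_os_comparator,
            "hr_pfs": None if t.hr_pfs is None else list(t.hr_pfs),
            "hr_os": None if t.hr_os is None else list(t.hr_os),
        }
    if cfg.provenance:
        doc["provenance"] = cfg.provenance
    return doc


def load_config(path) -> ModelConfig:
    """Load and validate a model configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def dump_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_reference_config() -> ModelConfig:
    """The bundled sorafenib-vs-BSC second-line mRCC parameterisation."""
    ref = resources.files("vbprice.fixtures").joinpath("sorafenib_rcc.yaml")
    with ref.open() as fh:
        return config_from_dict(yaml.safe_load(fh))


def replace(cfg, **kwargs):
    """dataclasses.replace re-export, handy for building scenario variants."""
    return dataclasses.replace(cfg, **kwargs)
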