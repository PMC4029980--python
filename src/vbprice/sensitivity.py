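"""One-way sensitivity analysis.

Each scenario perturbs exactly one parameter group of the model
configuration and reports two numbers: the value-based price re-solved under
the perturbed model at the base willingness-to-pay threshold, and the ICER
of the perturbed model with the drug price held at the base-case solved
price. (A drug-price scenario is the degenerate case: the "new price" is the
scaled price itself and the ICER is evaluated there.)

Perturbation rules keep each distribution family's uncertainty structure:
utility means shift with standard errors preserved (beta refit by moments);
cost means scale with the coefficient of variation held (a gamma keeps its
shape); survival effects act on the hazard scale — a +10% median
time-to-event improvement divides the affected monthly hazards by 1.1.
Survival effects modify the intervention arm (they represent treatment
effectiveness); overall-survival effects scale death hazards from both the
progression-free and the progressed state, which is flagged in the output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd
import yaml

from .params import (
    ArmSpec,
    DistributionSpec,
    ModelConfig,
    ParameterError,
    TransitionProbabilities,
    beta_from_mean_se,
    _point_of,
)
from .psa import run_psa
from .vbp import solve_vbp_price

__all__ = [
    "Scenario",
    "apply_scenario",
    "one_way_table",
    "load_scenarios",
    "load_reference_scenarios",
]

TARGETS = (
    "price",
    "horizon",
    "discount",
    "utilities",
    "medical_costs",
    "pfs_effect",
    "os_effect",
    "pfs_os_effect",
)


@dataclass(frozen=True)
class Scenario:
    """A single one-way perturbation.

    ``kind='set'`` replaces the parameter with ``value``; ``kind='scale'``
    multiplies it (for survival effects, ``value`` is the factor on median
    time-to-event, so hazards are divided by it).
    """

    name: str
    target: str
    kind: str
    value: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ParameterError(f"unknown scenario target {self.target!r}")
        if self.kind not in ("set", "scale"):
            raise ParameterError(f"scenario kind must be 'set' or 'scale', got {self.kind!r}")
        if self.kind == "scale" and self.value <= 0:
            raise ParameterError(f"scale factor must be positive, got {self.value}")


def _scale_utility(spec: DistributionSpec, factor: float) -> DistributionSpec:
    if spec.kind == "point":
        return DistributionSpec.point(spec.params[0] * factor)
    return beta_from_mean_se(spec.mean() * factor, spec.sd())


def _scale_cost(spec: DistributionSpec, factor: float) -> DistributionSpec:
    if spec.kind == "gamma":
        # mean *= factor at fixed CV: shape unchanged, rate /= factor
        return DistributionSpec.gamma(spec.params[0], spec.params[1] / factor)
    if spec.kind == "point":
        return DistributionSpec.point(spec.params[0] * factor)
    if spec.kind == "uniform":
        return DistributionSpec.uniform(spec.params[0] * factor, spec.params[1] * factor)
    raise ParameterError(f"cannot scale cost distribution of kind {spec.kind!r}")


def _scale_hazard_prob(p, median_factor: float):
    """Scale a monthly probability on the hazard scale.

    A ``median_factor`` of 1.1 (10% longer time-to-event) divides the hazard
    by 1.1: p' = 1 - (1-p)^(1/factor). Beta specs keep their pseudo-count
    total (alpha+beta) and shift their mean.
    """
    if isinstance(p, DistributionSpec):
        if p.kind == "point":
            return DistributionSpec.point(_scale_hazard_prob(p.params[0], median_factor))
        if p.kind != "beta":
            raise ParameterError(f"cannot hazard-scale distribution of kind {p.kind!r}")
        n = p.params[0] + p.params[1]
        new_mean = _scale_hazard_prob(p.mean(), median_factor)
        return DistributionSpec.beta(new_mean * n, (1.0 - new_mean) * n)
    return 1.0 - (1.0 - float(p)) ** (1.0 / median_factor)


def _modify_arm_costs(arm: ArmSpec, factor: float) -> ArmSpec:
    return dataclasses.replace(
        arm,
        cost_pfs_monthly=_scale_cost(arm.cost_pfs_monthly, factor),
        cost_pd_early_monthly=_scale_cost(arm.cost_pd_early_monthly, factor),
        cost_pd_late_monthly=_scale_cost(arm.cost_pd_late_monthly, factor),
    )


def _modify_arm_survival(arm: ArmSpec, factor: float, pfs: bool, os: bool) -> ArmSpec:
    tr = arm.transitions
    p_pd, p_d_pfs, p_d_pd = tr.p_pfs_to_pd, tr.p_pfs_to_death, tr.p_pd_to_death
    if pfs:
        p_pd = _scale_hazard_prob(p_pd, factor)
    if pfs or os:
        # death-from-PFS is both a PFS exit and a death hazard
        p_d_pfs = _scale_hazard_prob(p_d_pfs, factor)
    if os:
        p_d_pd = _scale_hazard_prob(p_d_pd, factor)
    return dataclasses.replace(
        arm,
        transitions=TransitionProbabilities(
            p_pfs_to_pd=p_pd, p_pfs_to_death=p_d_pfs, p_pd_to_death=p_d_pd
        ),
    )


def apply_scenario(cfg: ModelConfig, s: Scenario) -> ModelConfig:
    """Return a new config with the scenario applied (the input is untouched).

    A ``price`` scenario returns the config unchanged — the price is not a
    config parameter but the quantity the solver varies; `one_way_table`
    applies it to the base-case solved price.
    """
    if s.target == "price":
        return cfg
    if s.target == "horizon":
        if s.kind != "set":
            raise ParameterError("horizon scenarios must 'set' a cycle count")
        out = dataclasses.replace(cfg, horizon_cycles=int(s.value))
    elif s.target == "discount":
        if s.kind != "set":
            raise ParameterError("discount scenarios must 'set' a rate")
        out = dataclasses.replace(cfg, discount_annual=float(s.value))
    elif s.target == "utilities":
        factor = s.value if s.kind == "scale" else None
        if factor is None:
            raise ParameterError("utility scenarios must 'scale' the means")
        out = dataclasses.replace(
            cfg,
            utility_pfs=_scale_utility(cfg.utility_pfs, factor),
            utility_pd=_scale_utility(cfg.utility_pd, factor),
        )
    elif s.target == "medical_costs":
        if s.kind != "scale":
            raise ParameterError("cost scenarios must 'scale' the means")
        out = dataclasses.replace(
            cfg,
            intervention=_modify_arm_costs(cfg.intervention, s.value),
            comparator=_modify_arm_costs(cfg.comparator, s.value),
        )
    elif s.target in ("pfs_effect", "os_effect", "pfs_os_effect"):
        if s.kind != "scale":
            raise ParameterError("survival scenarios must 'scale' the median")
        pfs = s.target in ("pfs_effect", "pfs_os_effect")
        os_ = s.target in ("os_effect", "pfs_os_effect")
        out = dataclasses.replace(
            cfg,
            intervention=_modify_arm_survival(cfg.intervention, s.value, pfs, os_),
        )
    else:  # pragma: no cover - guarded by Scenario validation
        raise ParameterError(f"unhandled scenario target {s.target!r}")
    out.validate()
    return out


def one_way_table(
    cfg: ModelConfig,
    scenarios,
    base_vbp_price: float,
    wtp: float = 60_000.0,
    iterations: Optional[int] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Re-solved price and fixed-price ICER per scenario.

    ``new_price`` is the value-based price re-solved under the scenario at
    ``wtp``; ``icer`` evaluates the scenario model with the drug price fixed
    at ``base_vbp_price`` (price scenarios evaluate at their scaled price).
    """
    rows = []
    for s in scenarios:
        cfg_s = apply_scenario(cfg, s)
        note = s.note
        if s.target == "price":
            new_price = s.value * base_vbp_price if s.kind == "scale" else s.value
            icer_price = new_price
        else:
            res = solve_vbp_price(cfg_s, wtp, iterations=iterations, seed=seed)
            new_price = res.price
            icer_price = base_vbp_price
            if res.warnings:
                note = (note + "; " if note else "") + "; ".join(res.warnings)
        if s.target in ("os_effect", "pfs_os_effect"):
            note = (note + "; " if note else "") + (
                "OS effect scales death hazards from both PFS and PD"
            )
        icer = run_psa(cfg_s, icer_price, iterations=iterations, seed=seed).icer
        rows.append(
            {
                "scenario": s.name,
                "target": s.target,
                "kind": s.kind,
                "value": s.value,
                "new_price": new_price,
                "icer": icer,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def load_scenarios(path) -> list[Scenario]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [Scenario(**row) for row in doc["scenarios"]]


def load_reference_scenarios() -> list[Scenario]:
    """The bundled one-way scenario set for the sorafenib analysis."""
    ref = resources.files("vbprice.fixtures").joinpath("one_way_scenarios.yaml")
    with ref.open() as fh:
        doc = yaml.safe_load(fh)
    return [Scenario(**row) for row in doc["scenarios"]]
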