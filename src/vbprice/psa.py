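"""Probabilistic sensitivity analysis over the cohort model.

Parameters are drawn independently from their specified distributions
(straight Monte Carlo; with independent priors and no data-updating this is
exactly equivalent to a Gibbs scheme, so no burn-in is needed). Utilities are
state properties and one shared draw per iteration feeds both arms;
arm-specific transitions and costs are drawn independently.

The engine is vectorised across iterations: for each draw it propagates the
expanded 5-state occupancy for the full horizon and accumulates the
discounted expected months spent in each state, from which per-patient cost
and QALY follow as dot products with the drawn state costs and utilities.

The draw order is fixed (utilities, then intervention transitions/costs/drug
price, then comparator), so two runs from the same seed that differ only in
the drug price are driven by common random numbers — every other parameter,
and the drug price's underlying uniform deviate, are identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .markov import PFS, PD1, PD2, PD3, DEAD, N_STATES, discount_factors
from .params import ArmSpec, DistributionSpec, ModelConfig, ParameterError

__all__ = ["PsaResult", "sample_parameters", "run_psa", "convergence_report"]


def _draw(spec_or_value, rng: np.random.Generator, size):
    if isinstance(spec_or_value, DistributionSpec):
        return np.asarray(spec_or_value.sample(rng, size=size), dtype=float)
    return np.full(size, float(spec_or_value))


def _draw_arm(arm: ArmSpec, rng: np.random.Generator, size,
              drug_price_monthly=None) -> dict:
    tr = arm.transitions
    out = {
        "p_pfs_to_pd": _draw(tr.p_pfs_to_pd, rng, size),
        "p_pfs_to_death": _draw(tr.p_pfs_to_death, rng, size),
        "p_pd_to_death": _draw(tr.p_pd_to_death, rng, size),
        "cost_pfs": _draw(arm.cost_pfs_monthly, rng, size),
        "cost_pd_early": _draw(arm.cost_pd_early_monthly, rng, size),
        "cost_pd_late": _draw(arm.cost_pd_late_monthly, rng, size),
    }
    if arm.drug_cost_monthly is not None:
        spec = arm.drug_cost_monthly
        if drug_price_monthly is not None:
            spec = reprice(spec, drug_price_monthly)
        out["drug"] = _draw(spec, rng, size)
    else:
        out["drug"] = np.zeros(size)
    return out


def reprice(spec: DistributionSpec, price: float) -> DistributionSpec:
    """Move a drug-cost distribution to a candidate price.

    A uniform(lo, hi) keeps its spread and becomes uniform(price, price+hi-lo);
    anything else collapses to a point mass at the candidate price.
    """
    if price < 0:
        raise ParameterError(f"candidate drug price must be >= 0, got {price}")
    if spec.kind == "uniform":
        width = spec.params[1] - spec.params[0]
        return DistributionSpec.uniform(price, price + width)
    return DistributionSpec.point(price)


def sample_parameters(cfg: ModelConfig, rng: np.random.Generator,
                      drug_price_monthly=None, size: int = 1) -> dict:
    """One (or ``size``) concrete parameter set(s) drawn from the config.

    Returns nested dict: ``utilities`` (shared across arms) and one entry per
    arm keyed ``intervention`` / ``comparator``, each value an array of length
    ``size``. Point specs pass through unchanged.
    """
    draws = {
        "utilities": {
            "pfs": _draw(cfg.utility_pfs, rng, size),
            "pd": _draw(cfg.utility_pd, rng, size),
        },
        "intervention": _draw_arm(cfg.intervention, rng, size, drug_price_monthly),
        "comparator": _draw_arm(cfg.comparator, rng, size, None),
    }
    return draws


def _discounted_state_months(p_pd, p_d_pfs, p_d_pd, cycles: int, df: np.ndarray):
    """Discounted expected months per state, per draw: (n, 5) array.

    Occupancy is read at cycle start; entry ``t`` of ``df`` discounts cycle
    ``t+1``. Output rows are per-patient (initial occupancy 1 in PFS).
    """
    n = p_pd.shape[0]
    stay = 1.0 - p_pd - p_d_pfs
    if np.any(stay < -1e-12):
        bad = int(np.sum(stay < -1e-12))
        raise ParameterError(
            f"{bad} parameter draw(s) have PFS exit probabilities summing above 1"
        )
    stay = np.clip(stay, 0.0, 1.0)
    live = 1.0 - p_d_pd
    P = np.zeros((n, N_STATES, N_STATES))
    P[:, PFS, PFS] = stay
    P[:, PFS, PD1] = p_pd
    P[:, PFS, DEAD] = p_d_pfs
    P[:, PD1, PD2] = live
    P[:, PD1, DEAD] = p_d_pd
    P[:, PD2, PD3] = live
    P[:, PD2, DEAD] = p_d_pd
    P[:, PD3, PD3] = live
    P[:, PD3, DEAD] = p_d_pd
    P[:, DEAD, DEAD] = 1.0
    occ = np.zeros((n, 1, N_STATES))
    occ[:, 0, PFS] = 1.0
    W = np.zeros((n, N_STATES))
    for t in range(cycles):
        W += df[t] * occ[:, 0, :]
        occ = occ @ P
    return W


def _arm_outcomes(draws: dict, utilities: dict, cycles: int, df: np.ndarray,
                  cycles_per_year: int):
    W = _discounted_state_months(
        draws["p_pfs_to_pd"], draws["p_pfs_to_death"], draws["p_pd_to_death"],
        cycles, df,
    )
    cost = (
        W[:, PFS] * (draws["cost_pfs"] + draws["drug"])
        + (W[:, PD1] + W[:, PD2]) * draws["cost_pd_early"]
        + W[:, PD3] * draws["cost_pd_late"]
    )
    qaly = (
        W[:, PFS] * utilities["pfs"]
        + (W[:, PD1] + W[:, PD2] + W[:, PD3]) * utilities["pd"]
    ) / cycles_per_year
    return cost, qaly, W[:, PFS]


@dataclass(frozen=True)
class PsaResult:
    """Per-iteration (cost, QALY) draws for both arms plus run metadata.

    Column 0 of ``cost``/``qaly`` is the intervention arm, column 1 the
    comparator. ``pfs_months`` holds each draw's discounted expected months in
    PFS for the intervention arm (the affine slope of arm cost in drug price).
    """

    arm_names: tuple[str, str]
    cost: np.ndarray       # (iterations, 2)
    qaly: np.ndarray       # (iterations, 2)
    pfs_months: np.ndarray  # (iterations,)
    iterations: int
    seed: int
    drug_price_monthly: Optional[float] = None

    def _summ(self, x: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(x)),
            "lo": float(np.percentile(x, 2.5)),
            "hi": float(np.percentile(x, 97.5)),
        }

    @property
    def delta_cost(self) -> float:
        return float(np.mean(self.cost[:, 0]) - np.mean(self.cost[:, 1]))

    @property
    def delta_qaly(self) -> float:
        return float(np.mean(self.qaly[:, 0]) - np.mean(self.qaly[:, 1]))

    @property
    def icer(self) -> float:
        de = self.delta_qaly
        return self.delta_cost / de if de != 0 else float("nan")

    def summary(self) -> dict:
        out = {"arms": {}, "iterations": self.iterations, "seed": self.seed}
        for j, name in enumerate(self.arm_names):
            out["arms"][name] = {
                "cost": self._summ(self.cost[:, j]),
                "qaly": self._summ(self.qaly[:, j]),
            }
        out["incremental"] = {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
        }
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws table: iteration, arm, cost, qaly."""
        n = self.iterations
        return pd.DataFrame(
            {
                "iteration": np.tile(np.arange(n), 2),
                "arm": np.repeat(list(self.arm_names), n),
                "cost": np.concatenate([self.cost[:, 0], self.cost[:, 1]]),
                "qaly": np.concatenate([self.qaly[:, 0], self.qaly[:, 1]]),
            }
        )


def run_psa(
    cfg: ModelConfig,
    drug_price_monthly: Union[float, None] = None,
    iterations: Optional[int] = None,
    seed: Optional[int] = None,
) -> PsaResult:
    """Run the PSA: sample, simulate both arms per draw, summarise.

    ``drug_price_monthly=None`` uses the configured ("as-configured") drug
    cost distribution; a number moves that distribution to the candidate
    price (see :func:`reprice`). Deterministic given ``seed``.
    """
    n = int(iterations if iterations is not None else cfg.psa_iterations)
    if n < 1:
        raise ParameterError(f"iterations must be >= 1, got {n}")
    s = int(seed if seed is not None else cfg.seed)
    rng = np.random.default_rng(s)
    draws = sample_parameters(cfg, rng, drug_price_monthly, size=n)
    df = discount_factors(cfg.discount_annual, cfg.horizon_cycles, cfg.cycles_per_year)
    ci, qi, w_pfs = _arm_outcomes(
        draws["intervention"], draws["utilities"], cfg.horizon_cycles, df,
        cfg.cycles_per_year,
    )
    cc, qc, _ = _arm_outcomes(
        draws["comparator"], draws["utilities"], cfg.horizon_cycles, df,
        cfg.cycles_per_year,
    )
    return PsaResult(
        arm_names=(cfg.intervention.name, cfg.comparator.name),
        cost=np.column_stack([ci, cc]),
        qaly=np.column_stack([qi, qc]),
        pfs_months=w_pfs,
        iterations=n,
        seed=s,
        drug_price_monthly=drug_price_monthly,
    )


def convergence_report(result: PsaResult, grid_percent: int = 1) -> dict:
    """Monte-Carlo standard errors and running-mean traces.

    ``mc_se`` maps each summarised quantity to sample SD / sqrt(n); the
    ``running_means`` frame records cumulative means on a ``grid_percent``%%
    grid of the iteration count, the tabular analogue of a trace plot.
    """
    n = result.iterations
    if n < 100:
        raise ParameterError(f"convergence report needs >= 100 iterations, got {n}")
    quantities = {}
    for j, name in enumerate(result.arm_names):
        quantities[f"cost[{name}]"] = result.cost[:, j]
        quantities[f"qaly[{name}]"] = result.qaly[:, j]
    quantities["delta_cost"] = result.cost[:, 0] - result.cost[:, 1]
    quantities["delta_qaly"] = result.qaly[:, 0] - result.qaly[:, 1]
    mc_se = {
        k: float(np.std(v, ddof=1) / np.sqrt(n)) for k, v in quantities.items()
    }
    marks = np.unique(
        np.maximum(1, (np.arange(grid_percent, 101, grid_percent) / 100.0 * n))
        .astype(int)
    )
    rows = {"iterations": marks}
    for k, v in quantities.items():
        csum = np.cumsum(v)
        rows[k] = csum[marks - 1] / marks
    return {"mc_se": mc_se, "running_means": pd.DataFrame(rows)}
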