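"""Deterministic Markov cohort engine.

Five-state expanded state space: progression-free (PFS), three progressed
tunnel states (PD1, PD2 = first and second month after progression, PD3+ =
third month onwards) and absorbing Death. The tunnel states exist only so the
higher early-progression cost tier stays Markovian; they share one death
probability and one utility.

Conventions: the cohort enters in PFS; state membership is read at cycle
start and costs/QALYs accrue for the full cycle; cycle ``t`` (1-based) is
discounted by ``(1+r)^(-t/12)``; no half-cycle correction. Per-patient arm
cost is therefore exactly affine in the monthly drug price, with slope equal
to the discounted expected months spent in PFS — the property the
value-based-price solver exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ArmSpec, ModelConfig, ParameterError

__all__ = [
    "STATES",
    "build_transition_matrix",
    "simulate_cohort",
    "accumulate_outcomes",
    "discount_factors",
    "CohortTrace",
    "run_deterministic",
]

STATES = ("PFS", "PD1", "PD2", "PD3plus", "Dead")
N_STATES = len(STATES)
PFS, PD1, PD2, PD3, DEAD = range(N_STATES)
_ROW_TOL = 1e-12


def build_transition_matrix(
    p_pfs_to_pd: float, p_pfs_to_death: float, p_pd_to_death: float
) -> np.ndarray:
    """Row-stochastic 5x5 monthly transition matrix.

    PFS exits to PD1 or Death; PD1 -> PD2, PD2 -> PD3+, PD3+ self-loops, each
    with the common progressed-state death probability; Death is absorbing.
    """
    probs = (p_pfs_to_pd, p_pfs_to_death, p_pd_to_death)
    for name, p in zip(("p_pfs_to_pd", "p_pfs_to_death", "p_pd_to_death"), probs):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name} = {p} outside [0, 1]")
    if p_pfs_to_pd + p_pfs_to_death > 1.0 + _ROW_TOL:
        raise ParameterError(
            f"PFS exit probabilities sum to {p_pfs_to_pd + p_pfs_to_death} > 1"
        )
    stay_pfs = 1.0 - p_pfs_to_pd - p_pfs_to_death
    live_pd = 1.0 - p_pd_to_death
    m = np.array(
        [
            [stay_pfs, p_pfs_to_pd, 0.0, 0.0, p_pfs_to_death],
            [0.0, 0.0, live_pd, 0.0, p_pd_to_death],
            [0.0, 0.0, 0.0, live_pd, p_pd_to_death],
            [0.0, 0.0, 0.0, live_pd, p_pd_to_death],
            [0.0, 0.0, 0.0, 0.0, 1.0],
        ]
    )
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ParameterError(f"transition rows do not sum to 1: {m.sum(axis=1)}")
    return m


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy (persons) at the start of each cycle, rows 0..cycles."""

    occupancy: np.ndarray  # (cycles+1, 5)
    cohort_size: float

    @property
    def cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


def simulate_cohort(
    matrix: np.ndarray, cohort_size: float, cycles: int
) -> CohortTrace:
    """Propagate a cohort that enters entirely progression-free."""
    if cycles < 1:
        raise ParameterError(f"cycles must be >= 1, got {cycles}")
    occ = np.zeros((cycles + 1, N_STATES))
    occ[0, PFS] = cohort_size
    for t in range(cycles):
        occ[t + 1] = occ[t] @ matrix
    return CohortTrace(occupancy=occ, cohort_size=float(cohort_size))


def discount_factors(
    annual_rate: float, cycles: int, cycles_per_year: int = 12
) -> np.ndarray:
    """Vector of per-cycle discount factors for cycles 1..cycles."""
    t = np.arange(1, cycles + 1)
    return (1.0 + annual_rate) ** (-t / cycles_per_year)


def accumulate_outcomes(
    trace: CohortTrace,
    *,
    cost_pfs: float,
    cost_pd_early: float,
    cost_pd_late: float,
    utility_pfs: float,
    utility_pd: float,
    discount_annual: float,
    drug_price_monthly: float = 0.0,
    cycles_per_year: int = 12,
) -> tuple[float, float]:
    """Discounted per-patient (cost, QALY) totals for one arm.

    Utilities are annual weights; each monthly cycle contributes utility/12.
    The drug price accrues in PFS only.
    """
    if drug_price_monthly < 0:
        raise ParameterError(f"drug price must be non-negative, got {drug_price_monthly}")
    state_cost = np.array(
        [cost_pfs + drug_price_monthly, cost_pd_early, cost_pd_early, cost_pd_late, 0.0]
    )
    state_util = np.array(
        [utility_pfs, utility_pd, utility_pd, utility_pd, 0.0]
    ) / cycles_per_year
    occ = trace.occupancy[:-1]  # cycle-start membership, cycles 1..T
    df = discount_factors(discount_annual, trace.cycles, cycles_per_year)
    cost = float(df @ (occ @ state_cost)) / trace.cohort_size
    qaly = float(df @ (occ @ state_util)) / trace.cohort_size
    return cost, qaly


def _arm_point_outcomes(
    arm: ArmSpec, cfg: ModelConfig, drug_price_monthly=None
) -> tuple[float, float]:
    p_pd, p_d_pfs, p_d_pd = arm.transitions.point()
    matrix = build_transition_matrix(p_pd, p_d_pfs, p_d_pd)
    trace = simulate_cohort(matrix, cfg.cohort_size, cfg.horizon_cycles)
    if arm.drug_cost_monthly is None:
        price = 0.0
    elif drug_price_monthly is None:
        price = arm.drug_cost_monthly.mean()
    else:
        price = float(drug_price_monthly)
    return accumulate_outcomes(
        trace,
        cost_pfs=arm.cost_pfs_monthly.mean(),
        cost_pd_early=arm.cost_pd_early_monthly.mean(),
        cost_pd_late=arm.cost_pd_late_monthly.mean(),
        utility_pfs=cfg.utility_pfs.mean(),
        utility_pd=cfg.utility_pd.mean(),
        discount_annual=cfg.discount_annual,
        drug_price_monthly=price,
        cycles_per_year=cfg.cycles_per_year,
    )


def run_deterministic(cfg: ModelConfig, drug_price_monthly=None) -> dict:
    """Evaluate both arms at every distribution's mean (a zero-uncertainty run).

    ``drug_price_monthly`` overrides the intervention arm's drug acquisition
    price; by default the configured distribution's mean is used. Returns
    per-arm discounted cost/QALY per patient and the incremental statistics.
    """
    ci, qi = _arm_point_outcomes(cfg.intervention, cfg, drug_price_monthly)
    cc, qc = _arm_point_outcomes(cfg.comparator, cfg, None)
    out = {
        cfg.intervention.name: {"cost": ci, "qaly": qi},
        cfg.comparator.name: {"cost": cc, "qaly": qc},
        "delta_cost": ci - cc,
        "delta_qaly": qi - qc,
    }
    out["icer"] = (ci - cc) / (qi - qc) if qi != qc else float("nan")
    return out
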