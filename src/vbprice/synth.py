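"""Synthetic model configurations with the derivation chain real analyses use.

The generator emulates how a cost-utility model is parameterised from a
two-arm trial and a costing exercise: median progression-free and
post-progression survival times become monthly transition probabilities
through the constant-hazard conversion; binomially simulated event counts
become beta uncertainty around those probabilities; cost means with a
coefficient of variation become gamma specifications via the method of
moments; utility means with standard errors become beta specifications. The
result is a fully valid :class:`~vbprice.params.ModelConfig` plus the trial
summary it descends from, reproducible from the seed — so parameter-recovery
and solver round-trip tests never depend on the bundled reference fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import (
    ArmSpec,
    DistributionSpec,
    ModelConfig,
    ParameterError,
    TransitionProbabilities,
    TrialSummary,
    beta_from_counts,
    beta_from_mean_se,
    gamma_from_moments,
    monthly_risk_from_median,
    prob_from_rate,
    rate_from_median,
)
from .markov import run_deterministic
from .vbp import solve_vbp_price

__all__ = ["SyntheticSpec", "generate_config", "vbp_recovery_check"]

Range = tuple[float, float]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ranges the generator draws a study from (all months / euro / fractions).

    Defaults mirror a second-line oncology setting: a comparator progressing
    in a few months, an intervention roughly doubling that, post-progression
    survival around a year, monthly supportive-care costs in the hundreds of
    euro with a tight costing CV, and a four-figure monthly drug price.
    """

    seed: int = 0
    median_pfs_intervention: Range = (4.0, 8.0)
    median_pfs_comparator: Range = (2.0, 4.0)
    median_post_progression: Range = (8.0, 18.0)
    death_share_pfs: Range = (0.1, 0.35)  # share of the PFS-exit hazard that is death
    n_per_arm: tuple[int, int] = (200, 600)
    cost_pfs_mean: Range = (200.0, 500.0)
    cost_pd_early_mean: Range = (700.0, 1600.0)
    cost_pd_late_mean: Range = (500.0, 900.0)
    cost_cv: Range = (0.02, 0.2)
    utility_pfs_mean: Range = (0.70, 0.85)
    utility_pd_mean: Range = (0.55, 0.70)
    utility_se: Range = (0.02, 0.05)
    drug_price: Range = (2000.0, 3000.0)
    drug_price_spread: float = 20.0
    horizon_cycles: int = 120
    discount_annual: float = 0.035
    cohort_size: float = 1000.0
    wtp_thresholds: tuple[float, ...] = (20_000.0, 40_000.0, 60_000.0)
    psa_iterations: int = 2000

    def _check(self) -> None:
        for name in (
            "median_pfs_intervention",
            "median_pfs_comparator",
            "median_post_progression",
            "death_share_pfs",
            "n_per_arm",
            "cost_pfs_mean",
            "cost_pd_early_mean",
            "cost_pd_late_mean",
            "cost_cv",
            "utility_pfs_mean",
            "utility_pd_mean",
            "utility_se",
            "drug_price",
        ):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ParameterError(f"{name}: degenerate range ({lo}, {hi})")
            if lo <= 0 and name not in ("death_share_pfs",):
                raise ParameterError(f"{name}: range must be positive, got ({lo}, {hi})")
        if self.median_pfs_comparator[0] <= 0.5:
            raise ParameterError("comparator median PFS below half a cycle is degenerate")
        if not (0.0 < self.death_share_pfs[0] and self.death_share_pfs[1] < 1.0):
            raise ParameterError("death_share_pfs must lie strictly inside (0, 1)")
        if self.utility_pfs_mean[1] >= 1.0 or self.utility_pd_mean[1] >= 1.0:
            raise ParameterError("utility means must stay below 1")
        if self.drug_price_spread < 0:
            raise ParameterError("drug_price_spread must be non-negative")


def _u(rng: np.random.Generator, r: Range) -> float:
    return float(rng.uniform(r[0], r[1]))


def _beta_from_sim_counts(rng: np.random.Generator, p: float, n: int) -> DistributionSpec:
    events = int(np.clip(rng.binomial(n, p), 1, n - 1))
    return beta_from_counts(events, n)


def _synthetic_arm(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    name: str,
    median_pfs: float,
    median_pp: float,
    n: int,
    with_drug: bool,
) -> ArmSpec:
    share = _u(rng, spec.death_share_pfs)
    r_exit = rate_from_median(median_pfs)
    p_pd = prob_from_rate((1.0 - share) * r_exit)
    p_d_pfs = prob_from_rate(share * r_exit)
    p_d_pd = monthly_risk_from_median(median_pp)

    def cost(mean_range: Range) -> DistributionSpec:
        mean = _u(rng, mean_range)
        cv = _u(rng, spec.cost_cv)
        return gamma_from_moments(mean, (cv * mean) ** 2)

    drug = None
    if with_drug:
        lo = _u(rng, spec.drug_price)
        drug = DistributionSpec.uniform(lo, lo + spec.drug_price_spread)
    return ArmSpec(
        name=name,
        transitions=TransitionProbabilities(
            p_pfs_to_pd=_beta_from_sim_counts(rng, p_pd, n),
            p_pfs_to_death=_beta_from_sim_counts(rng, p_d_pfs, n),
            p_pd_to_death=_beta_from_sim_counts(rng, p_d_pd, n),
        ),
        cost_pfs_monthly=cost(spec.cost_pfs_mean),
        cost_pd_early_monthly=cost(spec.cost_pd_early_mean),
        cost_pd_late_monthly=cost(spec.cost_pd_late_mean),
        drug_cost_monthly=drug,
    )


#: a generated study must show at least this expected QALY gain, and its
#: zero-drug-price ICER must sit below this fraction of the lowest WTP
#: threshold, for the price inversion to be well posed at every threshold
MIN_DELTA_QALY = 0.02
MAX_ZERO_PRICE_ICER_FRACTION = 0.9
_MAX_ATTEMPTS = 1000


def generate_config(spec: SyntheticSpec) -> tuple[ModelConfig, TrialSummary]:
    """Draw one synthetic study and return its validated config + trial summary.

    The generator emulates trials of an *effective* intervention — the
    setting in which value-based pricing is meaningful. Candidate draws whose
    expected QALY gain is below :data:`MIN_DELTA_QALY`, or whose ICER at a
    zero drug price already exceeds the lowest WTP threshold (so no positive
    price could satisfy it), are rejected and redrawn from the same stream;
    the result is still deterministic given the seed.
    """
    spec._check()
    rng = np.random.default_rng(spec.seed)
    for _ in range(_MAX_ATTEMPTS):
        cfg, trial = _generate_candidate(rng, spec)
        det = run_deterministic(cfg, drug_price_monthly=0.0)
        if det["delta_qaly"] < MIN_DELTA_QALY:
            continue
        if det["delta_cost"] / det["delta_qaly"] > (
            MAX_ZERO_PRICE_ICER_FRACTION * min(spec.wtp_thresholds)
        ):
            continue
        return cfg, trial
    raise ParameterError(
        "could not draw a well-posed study from these ranges within "
        f"{_MAX_ATTEMPTS} attempts"
    )


def _generate_candidate(
    rng: np.random.Generator, spec: SyntheticSpec
) -> tuple[ModelConfig, TrialSummary]:
    m_pfs_i = _u(rng, spec.median_pfs_intervention)
    m_pfs_c = _u(rng, spec.median_pfs_comparator)
    m_pp_i = _u(rng, spec.median_post_progression)
    m_pp_c = _u(rng, spec.median_post_progression)
    n_i = int(rng.integers(spec.n_per_arm[0], spec.n_per_arm[1] + 1))
    n_c = int(rng.integers(spec.n_per_arm[0], spec.n_per_arm[1] + 1))

    intervention = _synthetic_arm(rng, spec, "intervention", m_pfs_i, m_pp_i, n_i, True)
    comparator = _synthetic_arm(rng, spec, "comparator", m_pfs_c, m_pp_c, n_c, False)

    u_pfs = _u(rng, spec.utility_pfs_mean)
    u_pd = min(_u(rng, spec.utility_pd_mean), u_pfs)
    se_pfs = _u(rng, spec.utility_se)
    se_pd = _u(rng, spec.utility_se)

    trial = TrialSummary(
        n_intervention=n_i,
        n_comparator=n_c,
        median_pfs_intervention=m_pfs_i,
        median_pfs_comparator=m_pfs_c,
        median_os_intervention=m_pfs_i + m_pp_i,
        median_os_comparator=m_pfs_c + m_pp_c,
        hr_pfs=(m_pfs_c / m_pfs_i, np.nan, np.nan),  # constant-hazard rate ratio
        hr_os=((m_pfs_c + m_pp_c) / (m_pfs_i + m_pp_i), np.nan, np.nan),
    )
    cfg = ModelConfig(
        intervention=intervention,
        comparator=comparator,
        utility_pfs=beta_from_mean_se(u_pfs, se_pfs),
        utility_pd=beta_from_mean_se(u_pd, se_pd),
        horizon_cycles=spec.horizon_cycles,
        cohort_size=spec.cohort_size,
        discount_annual=spec.discount_annual,
        wtp_thresholds=spec.wtp_thresholds,
        psa_iterations=spec.psa_iterations,
        seed=spec.seed,
        name=f"synthetic-{spec.seed}",
        trial=trial,
    )
    return cfg.validate(), trial


def vbp_recovery_check(
    cfg: ModelConfig,
    wtp: float,
    iterations: Optional[int] = None,
    seed: Optional[int] = None,
    tolerance: float = 0.01,
) -> dict:
    """Solve the value-based price and verify the ICER round trip.

    Returns the solved price, the confirmation ICER, the relative error
    |ICER - WTP| / WTP and whether it passes at ``tolerance``.
    """
    res = solve_vbp_price(cfg, wtp, iterations=iterations, seed=seed)
    rel = res.relative_icer_error
    return {
        "wtp": float(wtp),
        "price": res.price,
        "icer": res.icer,
        "relative_error": rel,
        "passed": bool(rel <= tolerance),
        "method": res.method,
        "warnings": list(res.warnings),
    }
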