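"""ICER computation and value-based price inversion.

The value-based price is the monthly drug acquisition price at which the
model ICER equals a willingness-to-pay threshold. Because drug cost accrues
only in the progression-free state, the intervention arm's mean cost is
exactly affine in the price (slope = mean discounted months in PFS), and the
incremental QALY gain does not depend on the price at all. The solver runs
the PSA at two anchor prices under common random numbers, fits the affine
incremental-cost line, and inverts ``dC(p) = WTP * dE`` in closed form; a
midpoint run checks the affinity assumption and triggers a bisection
fallback if it ever fails. A confirmation PSA at the solved price (same
seed, so the same draws) verifies the round trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .params import ModelConfig
from .psa import PsaResult, run_psa

__all__ = [
    "UndefinedIcerError",
    "compute_icer",
    "VbpResult",
    "solve_vbp_price",
    "threshold_table",
]

AFFINITY_RTOL = 1e-6


class UndefinedIcerError(ZeroDivisionError):
    """ICER requested for a zero incremental effect."""


def compute_icer(delta_cost: float, delta_qaly: float) -> float:
    """Incremental cost-effectiveness ratio, dC/dE (euro per QALY).

    A zero QALY difference leaves the ratio undefined; a negative one means
    one strategy dominates on effect and the ratio's usual decision reading
    breaks down, so a dominance warning is emitted.
    """
    if delta_qaly == 0:
        raise UndefinedIcerError("incremental QALYs are zero; ICER undefined")
    if delta_qaly < 0:
        warnings.warn(
            "negative incremental QALYs: intervention is dominated on effect; "
            "interpret the ratio with care",
            stacklevel=2,
        )
    return delta_cost / delta_qaly


@dataclass(frozen=True)
class VbpResult:
    """Solved value-based price and the confirmation run behind it."""

    wtp: float
    price: float
    delta_cost: float
    delta_qaly: float
    icer: float
    method: str                       # "affine" or "bisection"
    confirmation: PsaResult
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def relative_icer_error(self) -> float:
        return abs(self.icer - self.wtp) / self.wtp

    def summary(self) -> dict:
        s = self.confirmation.summary()
        return {
            "wtp": self.wtp,
            "price": self.price,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "method": self.method,
            "warnings": list(self.warnings),
            "arms": s["arms"],
        }


def solve_vbp_price(
    cfg: ModelConfig,
    wtp: float,
    iterations: Optional[int] = None,
    seed: Optional[int] = None,
    anchor_prices: tuple[float, float] = (1000.0, 3000.0),
    method: str = "auto",
) -> VbpResult:
    """Find the monthly drug price at which the ICER equals ``wtp``.

    ``method='auto'`` uses the affine closed form with a midpoint affinity
    check; ``'bisection'`` forces the root-finding fallback (useful as an
    independent cross-check). All PSA runs share one seed, so the solved
    price is exact up to the affinity of cost in price — no Monte-Carlo
    noise enters the inversion.
    """
    if wtp <= 0:
        raise ValueError(f"WTP threshold must be positive, got {wtp}")
    if cfg.intervention.drug_cost_monthly is None:
        raise ValueError("intervention arm has no drug-cost handle to solve for")
    notes: list[str] = []
    p1, p2 = anchor_prices
    r1 = run_psa(cfg, p1, iterations=iterations, seed=seed)
    r2 = run_psa(cfg, p2, iterations=iterations, seed=seed)
    de = r1.delta_qaly
    if abs(r2.delta_qaly - de) > 1e-9 * max(1.0, abs(de)):
        notes.append("incremental QALYs varied between anchor runs (CRN broken?)")
    slope = (r2.delta_cost - r1.delta_cost) / (p2 - p1)
    intercept = r1.delta_cost - slope * p1

    use_bisection = method == "bisection"
    if method == "auto":
        pm = 0.5 * (p1 + p2)
        rm = run_psa(cfg, pm, iterations=iterations, seed=seed)
        resid = abs(slope * pm + intercept - rm.delta_cost)
        if resid > AFFINITY_RTOL * max(1.0, abs(r2.delta_cost - r1.delta_cost)):
            notes.append(
                f"cost not affine in price (midpoint residual {resid:.3g}); "
                "falling back to bisection"
            )
            use_bisection = True

    if not use_bisection:
        price = (wtp * de - intercept) / slope
    else:
        def gap(p):
            r = run_psa(cfg, p, iterations=iterations, seed=seed)
            return r.delta_cost - wtp * r.delta_qaly

        lo, hi = 0.0, max(p2, 1000.0)
        g_lo = gap(lo)
        if g_lo > 0:
            # no non-negative root; extrapolate the (locally affine) gap line
            g1 = gap(hi)
            price = -g_lo * hi / (g1 - g_lo)
        else:
            g_hi = gap(hi)
            while g_hi < 0 and hi < 1e7:
                hi *= 2.0
                g_hi = gap(hi)
            price = float(brentq(gap, lo, hi, xtol=1e-6))

    if price < 0:
        notes.append(
            f"solved price {price:.2f} is negative: the intervention cannot reach "
            "the threshold at any non-negative price"
        )
        conf = run_psa(cfg, 0.0, iterations=iterations, seed=seed)
    else:
        conf = run_psa(cfg, price, iterations=iterations, seed=seed)
    icer = compute_icer(conf.delta_cost, conf.delta_qaly)
    return VbpResult(
        wtp=float(wtp),
        price=float(price),
        delta_cost=conf.delta_cost,
        delta_qaly=conf.delta_qaly,
        icer=icer,
        method="bisection" if use_bisection else "affine",
        confirmation=conf,
        warnings=tuple(notes),
    )


def threshold_table(
    cfg: ModelConfig,
    wtp_list=None,
    iterations: Optional[int] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Solved price and arm summaries per WTP threshold (CSV-serialisable)."""
    wtps = list(wtp_list if wtp_list is not None else cfg.wtp_thresholds)
    if not wtps:
        raise ValueError("need at least one WTP threshold")
    rows = []
    for wtp in wtps:
        res = solve_vbp_price(cfg, wtp, iterations=iterations, seed=seed)
        s = res.confirmation.summary()["arms"]
        i_name, c_name = res.confirmation.arm_names
        rows.append(
            {
                "wtp": wtp,
                "price": res.price,
                "cost_intervention": s[i_name]["cost"]["mean"],
                "cost_intervention_lo": s[i_name]["cost"]["lo"],
                "cost_intervention_hi": s[i_name]["cost"]["hi"],
                "cost_comparator": s[c_name]["cost"]["mean"],
                "cost_comparator_lo": s[c_name]["cost"]["lo"],
                "cost_comparator_hi": s[c_name]["cost"]["hi"],
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_qaly,
                "icer": res.icer,
                "method": res.method,
                "warnings": "; ".join(res.warnings),
            }
        )
    return pd.DataFrame(rows)
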