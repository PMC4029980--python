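"""One-way scenarios: parameter perturbation rules and the two-column table."""

import dataclasses

import pytest

from vbprice import (
    ParameterError,
    Scenario,
    apply_scenario,
    load_reference_scenarios,
    one_way_table,
    solve_vbp_price,
)


def test_reference_scenarios_load(ref_config):
    scens = load_reference_scenarios()
    assert len(scens) == 15
    targets = {s.target for s in scens}
    assert {"price", "horizon", "discount", "utilities", "medical_costs"} <= targets
    for s in scens:
        apply_scenario(ref_config, s).validate()


def test_discount_scenario_changes_only_discount(ref_config):
    out = apply_scenario(ref_config, Scenario("d0", "discount", "set", 0.0))
    assert out.discount_annual == 0.0
    assert dataclasses.replace(out, discount_annual=0.035) == ref_config


def test_horizon_scenario_five_years(ref_config):
    out = apply_scenario(ref_config, Scenario("h5", "horizon", "set", 60))
    assert out.horizon_cycles == 60


def test_utility_scenario_shifts_means_and_preserves_ses(ref_config):
    out = apply_scenario(ref_config, Scenario("u+", "utilities", "scale", 1.1))
    assert out.utility_pfs.mean() == pytest.approx(1.1 * ref_config.utility_pfs.mean(), rel=1e-12)
    assert out.utility_pd.mean() == pytest.approx(1.1 * ref_config.utility_pd.mean(), rel=1e-12)
    # the printed utility betas carry means 0.759992/0.680000, so the shifted
    # means land on 0.836/0.748 to ~1e-5
    assert out.utility_pfs.mean() == pytest.approx(0.836, abs=1e-4)
    assert out.utility_pd.mean() == pytest.approx(0.748, abs=1e-4)
    assert out.utility_pfs.sd() == pytest.approx(ref_config.utility_pfs.sd(), rel=1e-9)
    assert out.utility_pd.sd() == pytest.approx(ref_config.utility_pd.sd(), rel=1e-9)


def test_cost_scenario_scales_means_at_fixed_cv(ref_config):
    out = apply_scenario(ref_config, Scenario("c+", "medical_costs", "scale", 1.2))
    for arm_name in ("intervention", "comparator"):
        before = getattr(ref_config, arm_name)
        after = getattr(out, arm_name)
        for f in ("cost_pfs_monthly", "cost_pd_early_monthly", "cost_pd_late_monthly"):
            b, a = getattr(before, f), getattr(after, f)
            assert a.mean() == pytest.approx(1.2 * b.mean(), rel=1e-12)
            assert a.params[0] == b.params[0]  # gamma shape (CV) unchanged
    # the drug price is not a medical cost
    assert out.intervention.drug_cost_monthly == ref_config.intervention.drug_cost_monthly


def test_survival_scenario_scales_hazards_of_intervention_only(ref_config):
    out = apply_scenario(ref_config, Scenario("pfs+", "pfs_effect", "scale", 1.1))
    assert out.comparator == ref_config.comparator
    p_before = ref_config.intervention.transitions.p_pfs_to_pd
    p_after = out.intervention.transitions.p_pfs_to_pd
    expected = 1.0 - (1.0 - p_before.mean()) ** (1.0 / 1.1)
    assert p_after.mean() == pytest.approx(expected, rel=1e-9)
    # pseudo-count total (alpha+beta) preserved
    assert sum(p_after.params) == pytest.approx(sum(p_before.params), rel=1e-9)
    # PD death hazard untouched by a pure PFS effect
    assert out.intervention.transitions.p_pd_to_death == (
        ref_config.intervention.transitions.p_pd_to_death
    )


def test_os_scenario_scales_both_death_hazards(ref_config):
    out = apply_scenario(ref_config, Scenario("os+", "os_effect", "scale", 1.1))
    tr0, tr1 = ref_config.intervention.transitions, out.intervention.transitions
    assert tr1.p_pfs_to_pd == tr0.p_pfs_to_pd
    for before, after in ((tr0.p_pfs_to_death, tr1.p_pfs_to_death),
                          (tr0.p_pd_to_death, tr1.p_pd_to_death)):
        expected = 1.0 - (1.0 - before.mean()) ** (1.0 / 1.1)
        assert after.mean() == pytest.approx(expected, rel=1e-9)


def test_scenarios_do_not_mutate_and_invert_cleanly(ref_config):
    snapshot = dataclasses.replace(ref_config)
    up = apply_scenario(ref_config, Scenario("u+", "utilities", "scale", 1.1))
    back = apply_scenario(up, Scenario("u-", "utilities", "scale", 1.0 / 1.1))
    assert ref_config == snapshot
    assert back.utility_pfs.mean() == pytest.approx(ref_config.utility_pfs.mean(), rel=1e-12)
    assert back.utility_pfs.sd() == pytest.approx(ref_config.utility_pfs.sd(), rel=1e-12)

    down = apply_scenario(ref_config, Scenario("c-", "medical_costs", "scale", 0.8))
    restored = apply_scenario(down, Scenario("c+", "medical_costs", "scale", 1.25))
    assert restored.intervention.cost_pfs_monthly.params == pytest.approx(
        ref_config.intervention.cost_pfs_monthly.params, rel=1e-12
    )


def test_price_scenario_leaves_config_untouched(ref_config):
    s = Scenario("p-", "price", "scale", 0.5)
    assert apply_scenario(ref_config, s) == ref_config


@pytest.mark.parametrize(
    "scenario",
    [
        Scenario("bad", "utilities", "scale", 1.4),       # mean above 1
        Scenario("bad", "horizon", "scale", 0.5),         # horizon must be set
        Scenario("bad", "medical_costs", "set", 100.0),   # costs must scale
    ],
)
def test_invalid_scenarios_rejected(ref_config, scenario):
    with pytest.raises(ParameterError):
        apply_scenario(ref_config, scenario)


def test_unknown_target_rejected_at_construction():
    with pytest.raises(ParameterError):
        Scenario("bad", "gravity", "scale", 2.0)


def test_one_way_table_identity_and_price_rows(ref_config):
    base = solve_vbp_price(ref_config, 60_000.0, iterations=2000, seed=5)
    scens = [
        Scenario("identity", "medical_costs", "scale", 1.0),
        Scenario("price -50%", "price", "scale", 0.5),
    ]
    df = one_way_table(
        ref_config, scens, base.price, wtp=60_000.0, iterations=2000, seed=5
    )
    ident = df[df["scenario"] == "identity"].iloc[0]
    assert ident["new_price"] == pytest.approx(base.price, rel=1e-9)
    assert ident["icer"] == pytest.approx(60_000.0, rel=1e-6)
    half = df[df["scenario"] == "price -50%"].iloc[0]
    assert half["new_price"] == pytest.approx(base.price / 2.0, rel=1e-12)
    assert half["icer"] < 60_000.0


def test_one_way_rows_are_anti_monotone(ref_config):
    """A scenario that pushes the fixed-price ICER below the threshold must
    re-solve to a higher price, and vice versa (non-price rows)."""
    base = solve_vbp_price(ref_config, 60_000.0, iterations=2000, seed=5)
    scens = [
        Scenario("discount 0%", "discount", "set", 0.0),
        Scenario("utilities +10%", "utilities", "scale", 1.1),
        Scenario("utilities -10%", "utilities", "scale", 0.9),
        Scenario("horizon 5y", "horizon", "set", 60),
    ]
    df = one_way_table(
        ref_config, scens, base.price, wtp=60_000.0, iterations=2000, seed=5
    )
    for _, row in df.iterrows():
        assert (row["icer"] < 60_000.0) == (row["new_price"] > base.price), row["scenario"]
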