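import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from vbprice import (
    ArmSpec,
    DistributionSpec,
    ModelConfig,
    TransitionProbabilities,
    load_reference_config,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def _point(spec):
    if spec is None:
        return None
    return DistributionSpec.point(spec.mean())


def point_transitions(tr: TransitionProbabilities) -> TransitionProbabilities:
    p_pd, p_d_pfs, p_d_pd = tr.point()
    return TransitionProbabilities(p_pd, p_d_pfs, p_d_pd)


def point_arm(arm: ArmSpec) -> ArmSpec:
    return dataclasses.replace(
        arm,
        transitions=point_transitions(arm.transitions),
        cost_pfs_monthly=_point(arm.cost_pfs_monthly),
        cost_pd_early_monthly=_point(arm.cost_pd_early_monthly),
        cost_pd_late_monthly=_point(arm.cost_pd_late_monthly),
        drug_cost_monthly=_point(arm.drug_cost_monthly),
    )


def point_config(cfg: ModelConfig) -> ModelConfig:
    """Collapse every distribution to a point mass at its mean."""
    return dataclasses.replace(
        cfg,
        intervention=point_arm(cfg.intervention),
        comparator=point_arm(cfg.comparator),
        utility_pfs=_point(cfg.utility_pfs),
        utility_pd=_point(cfg.utility_pd),
    )


@pytest.fixture(scope="session")
def ref_config() -> ModelConfig:
    return load_reference_config()


@pytest.fixture(scope="session")
def ref_point_config(ref_config) -> ModelConfig:
    return point_config(ref_config)
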