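import numpy as np
import pandas as pd
import pytest

from metabodx.simulate import (
    CohortConfig,
    MetaboliteSpec,
    build_default_panel,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """Study-sized cohort (36 control / 76 case) with the default signature."""
    table, gt = generate_cohort(CohortConfig(seed=7), build_default_panel())
    return table, gt


@pytest.fixture(scope="session")
def null_cohort():
    """Age-balanced cohort with no group effects: labels carry no signal."""
    cfg = CohortConfig(
        n_control=36,
        n_case=76,
        control_age_dist=(34.0, 26.0, 44.0),
        case_age_dist=(34.0, 26.0, 44.0),
        seed=11,
        affected_metabolites=frozenset(),
    )
    table, gt = generate_cohort(cfg, build_default_panel())
    return table, gt


def flat_panel(n, baseline=100.0, slope=0.0, effect=0.0, cv=0.2, cls="other"):
    """Homogeneous panel of n metabolites for targeted generative checks."""
    return [
        MetaboliteSpec(
            name=f"M{i:03d}",
            class_label=cls,
            baseline=baseline,
            age_slope=slope,
            group_log2_effect=effect,
            noise_cv=cv,
        )
        for i in range(n)
    ]
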