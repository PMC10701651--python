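"""Shared fixtures: one default synthetic cohort and its derived assets.

The heavy artifacts (default cohort, web-network calibration, intervention
scenario sweep) are session-scoped so the statistical tests and the
plausibility checks share a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import peerdiffusion as pd_pkg
from peerdiffusion.abm_core import ModelParams, Population, build_influence_matrix
from peerdiffusion.calibration import grid_search, observed_class_means
from peerdiffusion.intervention import InterventionScenario, run_scenario
from peerdiffusion.network_builder import fas_table, pal_table
from peerdiffusion.sna_metrics import select_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

COHORT_SEED = 1


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (21 classes, sizes 15-27)."""
    return pd_pkg.generate_dataset(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def assets(cohort):
    """Networks, attribute tables, population and influence matrix."""
    web = pd_pkg.build_web_network(cohort.messages, cohort.roster)
    nomination = pd_pkg.build_nomination_network(cohort.nominations, cohort.roster)
    w1_pal = pal_table(cohort.steps, cohort.roster, [1])
    w5_pal = pal_table(cohort.steps, cohort.roster, [5])
    fas = fas_table(cohort.fas)
    population = Population.from_tables(cohort.roster, w5_pal, fas)
    base = ModelParams(t_pal=0.0, i_pal=0.0)
    return {
        "web": web,
        "nomination": nomination,
        "w1_pal": w1_pal,
        "w5_pal": w5_pal,
        "fas": fas,
        "population": population,
        "base_params": base,
        "W_web": build_influence_matrix(web, population, base),
        "observations": observed_class_means(cohort.steps, cohort.roster),
    }


@pytest.fixture(scope="session")
def web_calibration(cohort, assets):
    """Default-grid calibration of the web network (100 retained combos)."""
    return grid_search(
        assets["W_web"], assets["population"], assets["w1_pal"], cohort.roster,
        assets["observations"], seed=7,
    )


@pytest.fixture(scope="session")
def boost_sweep(cohort, assets, web_calibration):
    """Closeness-strategy intervention medians across the boost grid."""
    selection = select_cohort(
        assets["web"], assets["w5_pal"], "closeness", rng=np.random.default_rng(3)
    )
    out = {}
    for boost in (0.0, 0.05, 0.10, 0.17, 0.20):
        scenario = InterventionScenario(strategy="closeness", boost=boost, seed=11)
        out[boost] = run_scenario(
            scenario, web_calibration, assets["W_web"], assets["population"],
            assets["w1_pal"], cohort.roster, selection,
        )
    return out
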