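import dataclasses

import pytest

import divscan as d

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def scaled_config():
    return d.scaled_default_config()


@pytest.fixture(scope="session")
def scaled_cohort(scaled_config):
    """The 7-species, 28-chromosome scaled cohort at the default seed."""
    return d.simulate_cohort(scaled_config, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def scaled_results(scaled_cohort):
    """Full pipeline results on the scaled cohort."""
    return d.analyze_cohort(scaled_cohort)


@pytest.fixture(scope="session")
def tiny_config():
    """A 3-species, 4-chromosome miniature for fast stage tests."""
    chroms = [
        d.ChromPlan("c1", 400_000, micro=False),
        d.ChromPlan("c2", 300_000, micro=False),
        d.ChromPlan("c3", 100_000, micro=True),
        d.ChromPlan("c4", 100_000, micro=True),
    ]
    gene_plan = d.GenePlan(
        family_sizes={"OR": 30, "ZNF": 20, "OTHER": 100},
        cluster_factors={"OR": 10.0},
    )
    return d.SimConfig(
        species=["alpha", "beta", "gamma"],
        chroms=chroms,
        macro_threshold=200_000,
        baseline_het=1e-3,
        micro_het_multiplier=3.0,
        hotspots=[d.HotspotPlan("c3", 50_000, 100_000, het_multiplier=8.0, dist_multiplier=3.0)],
        roh_plans={"alpha": [d.ROHTract("c1", 0, 50_000)], "beta": [], "gamma": []},
        gene_plan=gene_plan,
        window_size=10_000,
        div_window_size=2_000,
        seed=11,
    ).validate()
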