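import numpy as np
import pandas as pd
import pytest

import spermethylome as sm


@pytest.fixture(scope="session")
def small_cohort():
    """Default-design cohort (7/7/6 subjects) on a reduced probe universe."""
    cfg = sm.SimulationConfig(
        n_probes=6000,
        timepoints_months=(0.0, 6.0, 12.0),
        pulse=sm.TreatmentPulse(n_sites=60, pool_overlap=0.25),
        rng_seed=7,
    )
    return sm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_baseline_cohort():
    """Baseline-only cohort on 40k probes: implanted signatures are sparse
    enough (~1.4% of probes) that random probe draws lack them."""
    cfg = sm.SimulationConfig(
        n_probes=40_000,
        timepoints_months=(0.0,),
        pulse=sm.TreatmentPulse(n_sites=0),
        rng_seed=19,
    )
    return sm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_differential(medium_baseline_cohort):
    co = medium_baseline_cohort
    model = sm.CohortDifferential(co.betas, co.manifest, co.annotation)
    return model, model.fit()


@pytest.fixture(scope="session")
def small_differential(small_cohort):
    co = small_cohort
    model = sm.CohortDifferential(co.betas, co.manifest, co.annotation)
    return model, model.fit()


@pytest.fixture()
def tiny_beta():
    beta = pd.DataFrame(
        {"s1": [0.1, 0.9], "s2": [0.2, np.nan]},
        index=pd.Index(["p1", "p2"], name="probe_id"),
    )
    return sm.BetaMatrix(beta)


@pytest.fixture()
def icr_regions():
    return sm.default_regions().icrs()
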