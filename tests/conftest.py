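import math

import numpy as np
import pytest

import occindex as oc


@pytest.fixture(scope="session")
def fixture_bundle():
    return oc.fixture_small()


@pytest.fixture(scope="session")
def small_bundle():
    """One moderate synthetic bundle shared across read-only tests."""
    return oc.generate_bundle(oc.SyntheticConfig(n_rows=12, n_cols=12, seed=7))


@pytest.fixture(scope="session")
def small_indicators(small_bundle):
    return oc.build_indicator_set(
        small_bundle.employment, small_bundle.scores, small_bundle.jem
    )


@pytest.fixture(scope="session")
def pr_coverage_experiment():
    """50 replicates of planted prevalence-ratio recovery at 2,000 tracts.

    Each replicate generates a bundle with a planted log PR of log(1.2),
    fits the stratified Poisson spline model with robust (HC1) errors, and
    records the between-stratum PR at 50% minority with its 95% CI.
    Session-scoped: both the calibration and the acceptance checks read it.
    """
    covered = 0
    log_ests = []
    for rep in range(50):
        cfg = oc.SyntheticConfig(n_rows=40, n_cols=50, seed=rep,
                                 planted_log_pr=math.log(1.2))
        b = oc.generate_bundle(cfg)
        ind = oc.build_indicator_set(b.employment, b.scores, b.jem)
        curve = oc.fit_stratified_pr(ind, b.context, "asthma", "pollutants_days",
                                     df=4, robust=True)
        est, lo, hi = curve.between_at(0.5)
        log_ests.append(math.log(est))
        covered += lo <= 1.2 <= hi
    return {"n": 50, "covered": covered, "log_ests": np.array(log_ests),
            "target": math.log(1.2)}
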