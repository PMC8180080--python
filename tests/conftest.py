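import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import uroscreen as u
from uroscreen.datamodel import CASE, CONTROL, CompoundRecord, ProfileMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_pm(abundance, groups, compound_meta=None) -> ProfileMatrix:
    """Build a ProfileMatrix from a plain array and group labels."""
    abundance = np.asarray(abundance, dtype=float)
    m, n = abundance.shape
    if compound_meta is None:
        compounds = [CompoundRecord(f"C{i}", f"compound {i}", 100 + i) for i in range(m)]
    else:
        compounds = compound_meta
    sample_ids = [f"S{j}" for j in range(n)]
    return ProfileMatrix(compounds, sample_ids, groups, abundance)


@pytest.fixture(scope="session")
def paper_like_run():
    """One full study-shaped discovery/evaluation run at a fixed seed.

    63 cases vs 61 controls, 922 compounds, 8 planted markers at a 3 log-sd
    shift with near-zero control detection, 8 contaminants; split 100/24,
    full LOOCV screen, panel fit and independent-cohort evaluation.
    """
    seed = 1234
    cfg = u.SyntheticConfig(seed=seed)
    pm, planted = u.generate_profile(cfg)
    split = u.split_cohorts(pm, 100, seed)
    pm_disc = pm.subset_samples(split.discovery_ids)
    pm_test = pm.subset_samples(split.test_ids)
    rounds = u.run_loocv(pm_disc, alpha=0.05, cutoff=0.6)
    marker_set = u.intersect_and_exclude(rounds, pm.compounds, pm_disc)
    performance = u.summarize_marker_performance(rounds, marker_set)
    panel = u.fit_logistic_panel(pm_disc, list(marker_set.marker_ids))
    test_roc = u.evaluate_panel(panel, pm_test)
    return {
        "config": cfg,
        "pm": pm,
        "planted": planted,
        "split": split,
        "pm_discovery": pm_disc,
        "pm_test": pm_test,
        "rounds": rounds,
        "marker_set": marker_set,
        "performance": performance,
        "panel": panel,
        "test_roc": test_roc,
    }
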