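import numpy as np
import pytest

from tlesustain import rois
from tlesustain.progression import build_event_set, expected_trajectory
from tlesustain.synthcohort import (CohortConfig, make_ground_truth,
                                    simulate_cohort, simulate_outcomes)
from tlesustain.zscoring import (compute_zscores, fit_normative,
                                 select_modeling_rois)


@pytest.fixture(scope="session")
def small_event_set():
    """3 biomarkers x 1 threshold: 6 valid orderings, cheap enumeration."""
    return build_event_set(["a", "b", "c"], (1.0,), z_max=3.0)


@pytest.fixture(scope="session")
def default_ground_truth():
    return make_ground_truth(seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_ground_truth):
    """Default-condition synthetic cohort (296 patients, 81 controls)."""
    gt = default_ground_truth
    morph, clin = simulate_cohort(gt, 296, 81, seed=12)
    clin = simulate_outcomes(gt, clin, seed=13)
    return gt, morph, clin


@pytest.fixture(scope="session")
def cohort_zscores(default_cohort):
    """(ground truth, modelled z-matrix of the patients) for recovery tests."""
    gt, morph, _ = default_cohort
    nm = fit_normative(morph[morph["group"] == "control"])
    Z = compute_zscores(nm, morph[morph["group"] == "patient"])
    return gt, select_modeling_rois(Z, list(rois.MODELING_ROIS))


def staged_zscores(es, order, stages, rng, sigma=1.0):
    """z-rows drawn on a known trajectory at given stages."""
    g = expected_trajectory(order, es)
    return g[:, stages].T + rng.normal(size=(len(stages), es.n_biomarkers)) * sigma
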