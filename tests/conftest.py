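import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qeeglda as q
from qeeglda.pipeline import fit_cohort, features_from_fits

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=25,
)
settings.load_profile("ci")


def cohort_features(groups, n_per_group, effect_scale, seed):
    """Direct-spectra cohort → fitted 132-column feature matrix."""
    cfg = q.CohortConfig(groups=groups, n_per_group=n_per_group,
                         effect_scale=effect_scale, mode="spectra")
    cohort = q.synthesize_cohort(cfg, seed=seed)
    fits = fit_cohort([s.spectra for s in cohort.subjects])
    return features_from_fits(fits, cohort.manifest), fits, cohort


@pytest.fixture(scope="session")
def hc_profile():
    return q.make_group_profile("HC", 1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 3-group direct-spectra cohort for structural tests."""
    cfg = q.CohortConfig(groups=("HC", "AD", "VaD"), n_per_group=4, mode="spectra")
    return q.synthesize_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def null_features():
    """Zero-effect HC/AD cohort at study size: groups are exchangeable."""
    feats, _, _ = cohort_features(("HC", "AD"), 114, 0.0, seed=101)
    return feats


@pytest.fixture(scope="session")
def mid_features():
    """Half-strength HC/AD cohort at study size."""
    feats, _, _ = cohort_features(("HC", "AD"), 114, 0.5, seed=102)
    return feats


@pytest.fixture(scope="session")
def full_cohort_features():
    """Default-strength three-group cohort (342 subjects) and its fit table."""
    feats, fits, cohort = cohort_features(("HC", "AD", "VaD"), 114, 1.0, seed=103)
    return feats, fits, cohort
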