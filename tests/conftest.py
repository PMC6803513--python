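import numpy as np
import pytest

from wmdisp.atlas import make_toy_atlas
from wmdisp.battery import default_battery
from wmdisp.synthetic import (
    BatterySimConfig,
    CohortConfig,
    ImagingSimConfig,
    default_test_params,
    make_study,
    simulate_battery_scores,
    simulate_cohort,
    simulate_skeleton_images,
)


@pytest.fixture(scope="session")
def battery():
    return default_battery()


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas()


@pytest.fixture(scope="session")
def cohort80(battery):
    """Default-condition cohort of 80 with scores and damage factor."""
    cohort, damage = simulate_cohort(CohortConfig(n_subjects=80, seed=101))
    scores = simulate_battery_scores(
        cohort, damage,
        BatterySimConfig(params=default_test_params(battery), seed=102),
        battery,
    )
    return cohort, damage, scores


@pytest.fixture(scope="session")
def imaging80(cohort80, toy_atlas):
    cohort, damage, _ = cohort80
    return simulate_skeleton_images(
        cohort, damage, ImagingSimConfig(seed=103), toy_atlas
    )


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A small synthetic study folder on disk (n=20)."""
    out = tmp_path_factory.mktemp("study")
    make_study(out, n_subjects=20, seed=7)
    return out
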