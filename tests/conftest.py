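import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import braincomplexity as bc


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced paired two-condition cohort (shared across tests for speed)."""
    spec = bc.SyntheticCohortSpec(
        n_subjects=4, n_regions=48, n_timepoints=160, seed=7
    )
    scans, meta, truth = bc.gen_cohort(spec)
    return spec, scans, meta, truth


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    spec, scans, meta, _ = small_cohort
    profiles = [
        bc.compute_profile(
            scans[(row.subject_id, row.condition)],
            row.subject_id,
            str(row.condition),
            row.dose,
        )
        for row in meta.itertuples()
    ]
    return bc.profiles_to_frame(profiles)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
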