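"""Shared fixtures: reference families and calibrated profiles are expensive
(Gumbel calibration runs 1000 null alignments per family), so they are built
once per session."""

import pytest

from hgscan.pipeline import build_profiles
from hgscan.synthetic import default_families


@pytest.fixture(scope="session")
def families():
    return default_families(seed=0)


@pytest.fixture(scope="session")
def profiles(families):
    return build_profiles(families, which=("hgcA", "hgcB", "recA"),
                          n_null=1000, calib_seed=0)


@pytest.fixture(scope="session")
def decoy_profile(families):
    from hgscan.profile import calibrate, profile_from_family
    return calibrate(profile_from_family(families["decoy"]), n_null=1000,
                     seed=0)
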