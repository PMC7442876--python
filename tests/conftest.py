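import numpy as np
import pytest

from rnflasym import (
    AngularField,
    CohortParams,
    EyeProfile,
    N_LOCATIONS,
    SubjectPair,
    default_params,
    generate_population,
    mirror_profile,
    normalize_and_difference,
    null_params,
)


def make_eye(
    laterality="OD",
    thickness=None,
    quality=30.0,
    n_bscans=80,
    scan_radius=1750.0,
):
    if thickness is None:
        thickness = np.full(N_LOCATIONS, 100.0)
    return EyeProfile(
        laterality=laterality,
        thickness=thickness,
        quality=quality,
        n_bscans=n_bscans,
        scan_radius=scan_radius,
    )


def make_pair(od_norm=None, os_norm=None, age=50.0, subject_id="S1", rd=0.0):
    """Build a pair from profiles given in the NORMALIZED frame."""
    if od_norm is None:
        od_norm = np.full(N_LOCATIONS, 100.0)
    if os_norm is None:
        os_norm = od_norm
    od = make_eye("OD", np.asarray(od_norm, dtype=float))
    os_ = make_eye("OS", mirror_profile(np.asarray(os_norm, dtype=float)), scan_radius=1750.0 + rd)
    return SubjectPair(subject_id, age, od=od, os=os_)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_population(default_params(n_subjects=80, seed=3))


@pytest.fixture(scope="session")
def small_diffs(small_cohort):
    return [normalize_and_difference(p) for p in small_cohort]


@pytest.fixture(scope="session")
def null_diffs():
    pairs = generate_population(null_params(n_subjects=60, seed=11))
    return [normalize_and_difference(p) for p in pairs]
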