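import numpy as np
import pytest

from remband import (
    BandProfile,
    CohortSpec,
    SyntheticCohort,
    generate_cohort,
    profile_from_rpsd,
    write_fixture,
)


def single_band_profile(band: str, sd: float = 1.0, **kw) -> BandProfile:
    band_sd = {b: 0.0 for b in ("delta", "theta", "alpha", "beta")}
    band_sd[band] = sd
    return BandProfile(band_sd=band_sd, **kw)


@pytest.fixture(scope="session")
def tiny_cohort() -> SyntheticCohort:
    """Two groups x one subject x three 30-s REM epochs, all five channels."""
    spec = CohortSpec(
        n_subjects_per_group=1,
        epochs_per_subject=3,
        seed=101,
        rem_block_epochs=2,  # forces a 2-epoch and a 1-epoch REM block
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_fixture_dir(tiny_cohort, tmp_path_factory):
    directory = tmp_path_factory.mktemp("cohort")
    write_fixture(tiny_cohort, directory)
    return directory


@pytest.fixture(scope="session")
def table3_profiles():
    """Group profiles targeting the reported group-mean relative band powers."""
    healthy = profile_from_rpsd(
        {"delta": 65.26, "theta": 20.619, "alpha": 8.424, "beta": 5.696},
        total_sd=10.0,
        drift_amp=2.0,
        hf_amp=0.5,
    )
    bruxism = profile_from_rpsd(
        {"delta": 65.302, "theta": 17.480, "alpha": 9.931, "beta": 7.287},
        total_sd=11.5,
        drift_amp=2.0,
        hf_amp=0.5,
    )
    return {"healthy": healthy, "bruxism": bruxism}
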