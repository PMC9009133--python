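from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from famseg.pedigree import hbm_study_pedigree

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_pedigree():
    """The six-member high-BMD family (3 affected / 3 unaffected)."""
    return hbm_study_pedigree()


@pytest.fixture()
def ped_file(tmp_path, study_pedigree) -> Path:
    from famseg.pedigree import write_pedigree

    path = tmp_path / "family.ped"
    write_pedigree(study_pedigree, path)
    return path
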