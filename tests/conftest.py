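import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from sulaniche import paper_like_preset, generate_isotopes


@pytest.fixture(scope="session")
def paper_like_samples():
    """One seeded draw of the full 8-cell synthetic design."""
    return generate_isotopes(paper_like_preset(), seed=20170301)


@pytest.fixture
def isotope_csv(tmp_path):
    """Factory writing a small isotope CSV and returning its path."""

    def _write(rows, header="sample_id,species,sex,tissue,year,d13c,d15n,c_n_ratio"):
        path = tmp_path / "isotopes.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write


@pytest.fixture
def diet_csv(tmp_path):
    def _write(rows, header="sample_id,species,total_mass_g,family,length_cm,complete"):
        path = tmp_path / "diet.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write
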