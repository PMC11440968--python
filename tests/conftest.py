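import pytest
from hypothesis import HealthCheck, settings

from bbbscreen import DescriptorProfile

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ideal_profile():
    """Every descriptor well inside the desirable ranges of both MPO models."""
    return DescriptorProfile(
        mw=300.0, clogp=2.0, clogd74=1.0, tpsa=55.0, hbd=0, hba=4,
        n_plus_o=4, pka_basic=7.0, aromatic_rings=2, heavy_atoms=22,
        polar_h=0, nitrogen_count=2, n_acid_base=1,
    )


@pytest.fixture
def poor_profile():
    """Every descriptor in undesirable territory."""
    return DescriptorProfile(
        mw=600.0, clogp=6.0, clogd74=5.0, tpsa=10.0, hbd=4, hba=9,
        n_plus_o=10, pka_basic=11.0, aromatic_rings=5, heavy_atoms=45,
        polar_h=5, nitrogen_count=4, n_acid_base=3,
    )
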