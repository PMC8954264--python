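import pytest

from lipoload import SizeDistribution, Suspension, Vesicle


@pytest.fixture
def vesicle_100nm() -> Vesicle:
    """A 100 nm vesicle with typical DSPC bilayer parameters."""
    return Vesicle(outer_diameter_nm=100.0, bilayer_thickness_nm=5.0,
                   area_per_lipid_nm2=0.45)


@pytest.fixture
def suspension_20mM() -> Suspension:
    """The concentrated protocol suspension: 20 mM lipid, 500 uL, 100 nm."""
    return Suspension(
        lipid_concentration_mM=20.0,
        volume_uL=500.0,
        distribution=SizeDistribution(mean_diameter_nm=100.0),
    )
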