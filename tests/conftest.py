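import numpy as np
import pytest

from ncs_atlas.synth import MotifPlant, RegionPlan, SyntheticLocusSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    """A scaled-down locus (~6 kb) for fast end-to-end tests."""
    return SyntheticLocusSpec(
        regions=(
            RegionPlan("promoter", 800, 0.45),
            RegionPlan("5ETS", 700, 0.80),
            RegionPlan("18S", 600, 0.56),
            RegionPlan("28S", 900, 0.69),
            RegionPlan("IGS", 3000, 0.45),
        ),
        plants=(
            MotifPlant("RLFS", "+", "promoter", 100, {"model": "m2"}),
            MotifPlant("G4", "+", "18S", 100),
            MotifPlant("G4", "-", "IGS", 500, {"tract_len": 4}),
            MotifPlant("iM", "+", "IGS", 1200),
            MotifPlant("iM", "-", "18S", 400, {"loop_len": 5}),
        ),
        locus_id="toy_locus",
    )
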