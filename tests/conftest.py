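import numpy as np
import pytest

import phenocloud as pc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_plant():
    """A small, well-separated noiseless plant with its ground truth."""
    spec = pc.SyntheticPlantSpec(
        stem_arc_length=12.0,
        stem_bend_angle_deg=10.0,
        leaf_specs=[
            pc.LeafSpec(midrib_arc_length=3.0, curl_angle_deg=40.0,
                        attachment_fraction=0.4, inclination_deg=30.0),
            pc.LeafSpec(midrib_arc_length=4.0, curl_angle_deg=90.0,
                        attachment_fraction=0.7, inclination_deg=25.0),
            pc.LeafSpec(midrib_arc_length=5.0, curl_angle_deg=120.0,
                        attachment_fraction=1.0, inclination_deg=35.0),
        ],
        noise_sigma=0.0,
        outlier_fraction=0.0,
        seed=42,
    )
    return pc.generate_plant(spec)


@pytest.fixture(scope="session")
def noisy_plant():
    """A paper-regime plant with sensor noise and sparse outliers."""
    spec = pc.paper_regime_spec(seed=11, stage=0.5)
    return pc.generate_plant(spec)
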