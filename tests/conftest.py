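import numpy as np
import pytest

from standcount.synthetic_fields import FieldSpec, generate_field


@pytest.fixture(scope="session")
def well_spaced_spec() -> FieldSpec:
    """A scene whose plants never touch: min spacing > 2 x mask radius."""
    return FieldSpec(
        width_px=256, height_px=256, row_spacing_cm=45.0, in_row_spacing_cm=20.0,
        missing_rate=0.0, touch_rate=0.0, weed_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_scene(well_spaced_spec):
    return generate_field(well_spaced_spec, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
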