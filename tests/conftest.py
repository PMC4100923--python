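import numpy as np
import pytest

from trirgb import ChannelSpec, GriddedField, SampleTable


@pytest.fixture
def small_field() -> GriddedField:
    """3x4 field with one masked cell, values 0..11."""
    vals = np.arange(12, dtype=float).reshape(3, 4)
    mask = np.ones((3, 4), dtype=bool)
    mask[0, 0] = False
    return GriddedField(
        values=vals, x_axis=np.array([0.0, 1.0, 2.0, 3.0]),
        y_axis=np.array([0.0, 10.0, 20.0]), units="µmol/L", name="NO3", mask=mask,
    )


@pytest.fixture
def nutrient_spec() -> ChannelSpec:
    return ChannelSpec(channel="red", source_name="NO3", norm_policy="zero_to_max",
                       gamma=0.5, c_min=0.0, c_max=16.0, units="µmol/L")


@pytest.fixture
def count_spec() -> ChannelSpec:
    return ChannelSpec(channel="blue", source_name="Pro", norm_policy="min_to_max",
                       gamma=1.0, c_min=100.0, c_max=1100.0, units="cells/mL")


@pytest.fixture
def plane_samples() -> SampleTable:
    """20 scattered points of the plane v = 2t + 3z + 1 (corners pinned)."""
    rng = np.random.default_rng(1234)
    t = rng.uniform(0.0, 100.0, 16)
    z = rng.uniform(0.0, 200.0, 16)
    t = np.concatenate([t, [0.0, 0.0, 100.0, 100.0]])
    z = np.concatenate([z, [0.0, 200.0, 0.0, 200.0]])
    return SampleTable(t=t, z=z, value=2.0 * t + 3.0 * z + 1.0, taxon="plane")
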