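import pytest

import spherestim as st


@pytest.fixture
def base8():
    """Canonical 8-sphere base stimulus."""
    return st.make_base(8, seed=42)


@pytest.fixture
def base8b():
    """A second, independent 8-sphere base."""
    return st.make_base(8, seed=43)


@pytest.fixture
def uniform_spec():
    return st.CategorySpec.uniform(
        position_shift=(0.05, 0.25),
        y_dev=(0.0, 0.2),
        size_dev=(0.02, 0.05),
        hue_dev=(0.0, 0.08),
        sat_dev=(0.0, 0.05),
        val_dev=(0.0, 0.05),
    )


@pytest.fixture
def gauss_spec():
    return st.CategorySpec.gauss(
        position_shift=0.12, y_dev=0.1, size_dev=0.02,
        hue_dev=0.04, sat_dev=0.03, val_dev=0.03,
    )


@pytest.fixture
def uniform_category(base8, uniform_spec):
    return st.generate_category(base8, uniform_spec, 50, seed=7)


@pytest.fixture
def gauss_category(base8, gauss_spec):
    return st.generate_category(base8, gauss_spec, 50, seed=8)
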