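import pytest

from afcea import load_parameters


@pytest.fixture(scope="session")
def base_params():
    """Base-case parameter set (built-in defaults)."""
    return load_parameters()


@pytest.fixture()
def quiet_params(base_params):
    """No events, no conversion, no discounting: closed-form dynamics."""
    return base_params.replace(
        p_stroke_aspirin=0.0,
        p_bleed_warfarin=0.0,
        p_convert_base=0.0,
        discount_rate=0.0,
        ranges={},
    )
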