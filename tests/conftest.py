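import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def trypsin():
    from pepscreen.proteolysis import parse_cleavage_rule

    return parse_cleavage_rule("trypsin: after {K,R} unless before {P}")


@pytest.fixture
def trypsin_cocktail(trypsin):
    from pepscreen.proteolysis import ProteaseCocktail

    return ProteaseCocktail((trypsin,))
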