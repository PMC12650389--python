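import pytest

from krillstruct.synthetic_fleet import default_paper_like_scenario, generate_fleet


@pytest.fixture(scope="session")
def small_fleet():
    """A down-scaled six-season fleet (~5% of the reference design) for
    fast pipeline-level tests."""
    scen = default_paper_like_scenario(seed=7).scaled(0.05)
    scen.seed = 7
    return generate_fleet(scen)


@pytest.fixture(scope="session")
def paper_fleet():
    """The full reference design: 4491 hauls, 811 measured, 200 lengths each."""
    scen = default_paper_like_scenario(seed=1)
    return generate_fleet(scen)
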