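import pytest
from hypothesis import HealthCheck, settings

from seqdigit.seqio import FixtureConfig, make_strain_family

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def family():
    """Default synthetic strain family: five ~1.5 kb ingroup records at
    ~99% identity plus a ~97%-identical outgroup."""
    return make_strain_family()


@pytest.fixture(scope="session")
def small_family():
    """A faster family (~600 nt) with the same ingroup/outgroup structure."""
    return make_strain_family(FixtureConfig(
        n_strains=4, length_range=(580, 620), gc_target=0.535,
        divergence=0.02, outgroup_divergence=0.06, seed=11))


@pytest.fixture(scope="session")
def small_msa(small_family):
    from seqdigit.alignment import complete_deletion, progressive_align

    msa = progressive_align(small_family)
    filtered, retained = complete_deletion(msa)
    return msa, filtered, retained
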