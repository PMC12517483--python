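import pytest

from traitarch.demography import constant_demography, preset
from traitarch.sfs import build_cache
from traitarch.simulate import TraitScenario, simulate_trait
from traitarch.trait import SelectionDensity


@pytest.fixture(scope="session")
def const_cache():
    """Conditional SFS under constant N = 10,000 (closed-form territory)."""
    return build_cache(constant_demography(10_000))


@pytest.fixture(scope="session")
def ukb_cache():
    """Conditional SFS under the bottleneck-plus-growth default history."""
    return build_cache(preset("ukb-default"))


@pytest.fixture(scope="session")
def ssd_fs():
    return SelectionDensity.preset("ssd-like")


@pytest.fixture(scope="session")
def canonical_scenario():
    """~500-expected-hit trait at the canonical study conditions."""
    return TraitScenario("canon", fs="ssd-like", h2_over_L=3e-8, L=8.3e6,
                         n=3e5, seed=20260921)


@pytest.fixture(scope="session")
def canonical_data(canonical_scenario, ukb_cache):
    arch, hits = simulate_trait(canonical_scenario, cache=ukb_cache)
    return arch, hits


@pytest.fixture(scope="session")
def canonical_hits(canonical_data):
    return canonical_data[1]


@pytest.fixture(scope="session")
def canonical_fit(canonical_hits, ukb_cache):
    from traitarch.inference import FitConfig, fit_tsd

    return fit_tsd(canonical_hits, ukb_cache, FitConfig(n_starts=4, seed=0))
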