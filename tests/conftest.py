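import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from proteotyper.simulate import FixtureSpec, generate_proteomes

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_collection():
    """Compact hierarchical collection: 2 phyla x 2 genera x 3 species x 2 strains."""
    spec = FixtureSpec(
        n_phyla=2,
        n_genera_per_phylum=2,
        n_species_per_genus=3,
        n_strains_per_species=2,
        proteins_per_proteome=10,
        mean_protein_len=150,
        seed=11,
    )
    return generate_proteomes(spec)


@pytest.fixture(scope="session")
def default_collection():
    """The default-sized collection used for end-to-end benchmarks."""
    return generate_proteomes(FixtureSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
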