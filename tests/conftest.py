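import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mitobipart.reference import load_reference_annotations
from mitobipart.synthetic_data import generate_bipartite_genome, reference_bipartite_spec


@pytest.fixture(scope="session")
def reference_annotations():
    """Both transcribed published chromosome tables (no sequences)."""
    return load_reference_annotations()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One deterministic synthetic bipartite genome with 3 planted substitutions."""
    spec = reference_bipartite_spec(k_substitutions=3, seed=20260924)
    return generate_bipartite_genome(spec)
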