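import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kb():
    from shunt_ledger.reaction_kb import default_reaction_set
    return default_reaction_set()


@pytest.fixture(scope="session")
def pathways():
    from shunt_ledger.composer import BUNDLED_PATHWAYS, bundled_pathway
    return {name: bundled_pathway(name) for name in BUNDLED_PATHWAYS}


@pytest.fixture(scope="session")
def profiles():
    from shunt_ledger.transcriptomics import load_model_profiles
    return load_model_profiles()


@pytest.fixture(scope="session")
def genesets():
    from shunt_ledger.transcriptomics import load_genesets
    return load_genesets()
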