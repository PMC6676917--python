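import pytest

from cdmdq import (load_catalog, load_schema_manifest)
from cdmdq.checks import default_vocabulary
from cdmdq.synth import SynthProfile, generate_clean, make_reference_context


@pytest.fixture(scope="session")
def manifest():
    return load_schema_manifest()


@pytest.fixture(scope="session")
def catalog(manifest):
    return load_catalog(manifest=manifest)


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def small_profile():
    return SynthProfile(n_persons=200, seed=5)


@pytest.fixture(scope="session")
def clean_small(small_profile, manifest):
    return generate_clean(small_profile, manifest)


@pytest.fixture(scope="session")
def ctx_small(small_profile):
    return make_reference_context(small_profile)


@pytest.fixture(scope="session")
def check_key(catalog):
    """Map check_id -> (alias, table, primary field or None)."""
    out = {}
    for c in catalog.checks:
        ts = catalog.type_of(c)
        f = c.field if ts.scope in ("field", "field_pair") else None
        out[c.check_id] = (c.type_alias, c.table, f)
    return out
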