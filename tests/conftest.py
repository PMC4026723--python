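import pytest

import cpg_descent as cd


@pytest.fixture(scope="session")
def tree():
    return cd.default_tree()


@pytest.fixture(scope="session")
def segments():
    return cd.default_segments()


@pytest.fixture(scope="session")
def taxa(tree):
    return tree.taxa


def presence(taxa, present, site_id="s1"):
    """Presence vector with the given taxa present, all others absent."""
    return cd.PresenceVector(
        site_id,
        {t: (cd.PRESENT if t in present else cd.ABSENT) for t in taxa},
    )


@pytest.fixture
def make_presence(taxa):
    def _make(present, site_id="s1"):
        return presence(taxa, present, site_id)

    return _make
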