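import pytest

from minidol.dol import flatten
from minidol.fixtures import build_her2, build_mereology


@pytest.fixture(scope="session")
def mereology():
    return build_mereology()


@pytest.fixture(scope="session")
def her2_doc():
    return build_her2("reconciled")


@pytest.fixture(scope="session")
def her2(her2_doc):
    return flatten(her2_doc, "HER2")


@pytest.fixture(scope="session")
def flat(mereology):
    """Flattened mereology modules by name."""
    return {name: flatten(mereology, name) for name in mereology.modules}
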