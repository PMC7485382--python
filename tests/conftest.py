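import pytest

from vfspace import build_basis, uniform_state


@pytest.fixture
def abc_basis():
    """The three-item worked example basis over {A, B, C}."""
    return build_basis(["A", "B", "C"])


@pytest.fixture
def abc_uniform(abc_basis):
    """Uniform initial state |x> over the three-item basis."""
    return uniform_state(abc_basis)
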