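import numpy as np
import pytest

from orbitpanel import BinaryPanel, SubjectSeries, example_subjects


@pytest.fixture(scope="session")
def demo() -> SubjectSeries:
    """The 8-observation, 3-variable demonstration subject."""
    return example_subjects()["demo"]


@pytest.fixture(scope="session")
def trio() -> dict:
    """The three 5-observation demonstration subjects."""
    ex = example_subjects()
    return {k: ex[k] for k in ("trio_a", "trio_b", "trio_c")}


def random_panel(rng: np.random.Generator, n: int, p: int, T: int) -> BinaryPanel:
    """Uniform random complete binary panel (test helper)."""
    values = rng.integers(0, 2, size=(n, p, T + 1))
    return BinaryPanel(
        values,
        [f"s{i}" for i in range(n)],
        [f"Q{i}" for i in range(p)],
        list(range(T + 1)),
    )
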