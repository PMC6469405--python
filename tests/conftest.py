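import numpy as np
import pytest

import errblup as eb


@pytest.fixture
def demo():
    """Five lines x two markers with phenotypes (the worked example)."""
    return eb.two_locus_demo()


@pytest.fixture
def demo_design(demo):
    M, y = demo
    monos = eb.enumerate_monomials(2, degree=2)
    return eb.build_design(M, monos), y, monos


def random_instance(seed, n=30, p=4, shift_scale=1.0):
    """A generic random regression instance plus a random translation."""
    rng = np.random.default_rng(seed)
    M = eb.MarkerMatrix(rng.integers(0, 3, size=(n, p)).astype(float),
                        [f"l{i}" for i in range(n)],
                        [f"m{j}" for j in range(p)])
    y = rng.standard_normal(n)
    P = shift_scale * rng.standard_normal(p)
    return M, y, P
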