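import numpy as np
import pytest

from zygld import TwoLocusCounts, rug_genotype_probs, admixture_genotype_probs


@pytest.fixture
def w1_counts():
    """Perfect coupling fixture: 50 AABB + 50 aabb animals."""
    P = np.zeros((3, 3))
    P[2, 2] = P[0, 0] = 50
    return TwoLocusCounts(counts=P, n=100)


@pytest.fixture
def rug_d01_probs():
    """Exact genotype table under random union of gametes, D=0.1, p=q=0.5."""
    return rug_genotype_probs([0.35, 0.15, 0.15, 0.35])


@pytest.fixture
def independent_probs():
    """Product of HWE margins at p_A = p_B = 0.5: full independence."""
    m = np.array([0.25, 0.5, 0.25])
    return np.outer(m, m)


@pytest.fixture
def mix7030_probs():
    """70/30 mixture of HWE breeds with p = 0.9 / 0.1 at both (unlinked) loci."""
    return admixture_genotype_probs([0.9, 0.1], [0.9, 0.1], [0.7, 0.3])
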