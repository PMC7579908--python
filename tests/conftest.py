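import logging

import numpy as np
import pytest

from ncmhap import SNPMatrix

# the center-update "zero-weight column" warning is expected on sparse toys
logging.getLogger("ncmhap.ncm").setLevel(logging.ERROR)


@pytest.fixture
def separable_matrix() -> SNPMatrix:
    """Six noise-free fragments, three per chromosome copy."""
    return SNPMatrix.from_strings(["0101"] * 3 + ["1010"] * 3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_matrix(rng: np.random.Generator, m: int, n: int, gap: float = 0.3) -> SNPMatrix:
    """Random valid SNP matrix: every row keeps at least one observed site."""
    while True:
        alleles = rng.integers(0, 2, size=(m, n)).astype(np.uint8)
        observed = rng.random((m, n)) >= gap
        if observed.any(axis=1).all():
            return SNPMatrix(alleles, observed)
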