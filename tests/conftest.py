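import numpy as np
import pytest

from sclc.phenocorr import CorrelationMatrix, normalize_and_repair
from sclc.simulate import ar1_block_R


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_corr():
    """Factory for random well-conditioned correlation matrices."""

    def make(K, seed):
        r = np.random.default_rng(seed)
        A = r.standard_normal((K, K + 4))
        return normalize_and_repair(np.corrcoef(A))

    return make


@pytest.fixture(scope="session")
def R40():
    return ar1_block_R(40, 0.1)


@pytest.fixture
def equicorr():
    def make(K, rho):
        R = np.full((K, K), rho) + (1 - rho) * np.eye(K)
        return CorrelationMatrix.from_values(R)

    return make


def write_sumstats_file(path, rows, header="SNP CHR BP A1 A2 Z N"):
    """Write a tiny whitespace-delimited summary-statistics file."""
    lines = [header] + [" ".join(str(x) for x in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
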