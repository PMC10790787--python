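import math

import pytest

from toxscan import scan_genome, thauera_fixture
from toxscan.island_scan import passing_islands


def poisson_tail_bruteforce(k: int, lam: float, terms: int = 400) -> float:
    """Independent upper-tail Poisson oracle: direct pmf summation in log
    space with exact compensated addition."""
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    total = []
    for j in range(k, k + terms):
        log_pmf = -lam + j * math.log(lam) - math.lgamma(j + 1)
        total.append(math.exp(log_pmf))
    return min(1.0, math.fsum(total))


@pytest.fixture(scope="session")
def thauera():
    return thauera_fixture()


@pytest.fixture(scope="session")
def thauera_islands(thauera):
    return scan_genome(thauera)


@pytest.fixture(scope="session")
def thauera_passing(thauera_islands):
    return passing_islands(thauera_islands)
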