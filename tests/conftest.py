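import io

import numpy as np
import pytest

from bandpop.matrix import BandMatrix, read_band_matrix
from bandpop.simulate import simulate_island


@pytest.fixture
def toy_csv() -> str:
    return (
        "individual,population,L1,L2,L3\n"
        "a1,A,1,0,1\n"
        "a2,A,1,1,0\n"
        "b1,B,0,0,1\n"
        "b2,B,0,1,1\n"
    )


@pytest.fixture
def toy_matrix(toy_csv) -> BandMatrix:
    return read_band_matrix(io.StringIO(toy_csv))


@pytest.fixture(scope="session")
def island_matrix():
    """Moderate-differentiation island dataset shared across tests."""
    m, truth = simulate_island(K=4, N=25, L=80, theta_true=0.2, seed=11)
    return m, truth


def two_pop_single_locus(n1_present: int, n1_absent: int,
                         n2_present: int, n2_absent: int) -> BandMatrix:
    """One-locus matrix realising a 2x2 phenotype x population table."""
    rows, pops = [], []
    for pop, pres, abs_ in (("A", n1_present, n1_absent), ("B", n2_present, n2_absent)):
        rows += [[1]] * pres + [[0]] * abs_
        pops += [pop] * (pres + abs_)
    inds = [f"i{k}" for k in range(len(rows))]
    return BandMatrix(inds, pops, ["L1"], np.array(rows, dtype=np.int8))
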