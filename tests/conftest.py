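"""Shared fixtures and independent oracles."""
import math

import numpy as np
import pytest

from tgxlink.chem import Peptide, make_pair

# Independent residue mass reference for oracle computations (typed in from a
# standard monoisotopic table, NOT imported from the package under test).
ORACLE_RESIDUES = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_WATER = 18.01056
ORACLE_PROTON = 1.00728
ORACLE_AMMONIA = 17.02655


def oracle_peptide_mass(sequence: str, mod_deltas=()) -> float:
    return sum(ORACLE_RESIDUES[r] for r in sequence) + ORACLE_WATER + sum(mod_deltas)


def oracle_binomial_tail(n: int, k: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, j) * p**j * (1.0 - p) ** (n - j) for j in range(k, n + 1))


@pytest.fixture
def alpha_peptide() -> Peptide:
    return Peptide("EGGKGPR", "model_collagen", 893, 899, missed_cleavages=1)


@pytest.fixture
def beta_peptide() -> Peptide:
    return Peptide("SQDGGR", "model_collagen", 1198, 1203)


@pytest.fixture
def txlp(alpha_peptide, beta_peptide):
    """The model cross-linked pair: EGGKGPR(K4) x SQDGGR(Q2)."""
    return make_pair(alpha_peptide, beta_peptide, k_pos=4, q_pos=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
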