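"""Monoisotopic mass model for peptides, modifications and the Lys-Gln isopeptide cross-link.

The cross-link is modelled as a condensation of a glutamine side-chain amide
with a lysine epsilon-amine, i.e. the pair mass is the sum of the two peptide
masses minus one ammonia (17.026549 Da).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Tuple

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "AMMONIA_MASS",
    "MONOISOTOPIC_RESIDUE_MASSES",
    "ResidueMassTable",
    "DEFAULT_MASS_TABLE",
    "Modification",
    "Peptide",
    "CrossLinkedPair",
    "InvalidSequenceError",
    "InvalidChargeError",
    "peptide_mass",
    "pair_mass",
    "mz",
    "make_pair",
    "CARBAMIDOMETHYL_C",
    "OXIDATION_M",
    "DEAMIDATION_Q",
]

PROTON_MASS = 1.007276
WATER_MASS = 18.010565
#: Neutral loss of the isopeptide condensation (NH3).
AMMONIA_MASS = 17.026549

MONOISOTOPIC_RESIDUE_MASSES: Mapping[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains a residue absent from the mass table."""


class InvalidChargeError(ValueError):
    """Raised when an m/z is requested for a non-positive charge."""


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus the constant masses of the model."""

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(MONOISOTOPIC_RESIDUE_MASSES)
    )
    water_mass: float = WATER_MASS
    proton_mass: float = PROTON_MASS
    ammonia_mass: float = AMMONIA_MASS

    def residue(self, letter: str) -> float:
        try:
            return self.residue_masses[letter]
        except KeyError:
            raise InvalidSequenceError(f"unknown residue {letter!r}") from None

    def validate(self, sequence: str) -> None:
        for letter in sequence:
            if letter not in self.residue_masses:
                raise InvalidSequenceError(
                    f"unknown residue {letter!r} in sequence {sequence!r}"
                )


DEFAULT_MASS_TABLE = ResidueMassTable()

N_TERM = "N-term"
C_TERM = "C-term"


@dataclass(frozen=True)
class Modification:
    """A fixed or variable mass modification targeting one residue or terminus."""

    name: str
    target: str  # residue letter or N_TERM / C_TERM
    delta_mass: float
    variable: bool = True

    def __post_init__(self) -> None:
        if not (self.delta_mass == self.delta_mass):  # NaN guard
            raise ValueError("delta_mass must be finite")
        ok = self.target in MONOISOTOPIC_RESIDUE_MASSES or self.target in (N_TERM, C_TERM)
        if not ok:
            raise ValueError(f"invalid modification target {self.target!r}")


CARBAMIDOMETHYL_C = Modification("carbamidomethyl", "C", 57.021464, variable=False)
OXIDATION_M = Modification("oxidation", "M", 15.994915, variable=True)
DEAMIDATION_Q = Modification("deamidation", "Q", 0.984016, variable=True)


@dataclass(frozen=True)
class Peptide:
    """A digested peptide with provenance coordinates (1-based, inclusive)."""

    sequence: str
    protein_id: str
    start: int
    end: int
    missed_cleavages: int = 0
    modifications: Tuple[Tuple[int, Modification], ...] = ()
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates {self.start}-{self.end} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )
        for pos, mod in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside 1..{len(self.sequence)}")
            if mod.target not in (N_TERM, C_TERM) and self.sequence[pos - 1] != mod.target:
                raise ValueError(
                    f"modification {mod.name} targets {mod.target}, "
                    f"but position {pos} is {self.sequence[pos - 1]}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def modified_at(self, pos: int) -> bool:
        return any(p == pos for p, _ in self.modifications)

    def with_modifications(self, mods: Tuple[Tuple[int, Modification], ...]) -> "Peptide":
        return replace(self, modifications=mods)

    @property
    def key(self):
        """Identity of the peptide variant, used for deduplication."""
        return (
            self.protein_id,
            self.start,
            self.end,
            self.sequence,
            self.modifications,
            self.is_decoy,
        )


def peptide_mass(p: Peptide, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """Neutral monoisotopic mass: residue sum + water + modification deltas."""
    table.validate(p.sequence)
    mass = table.water_mass + sum(table.residue(r) for r in p.sequence)
    mass += sum(mod.delta_mass for _, mod in p.modifications)
    return mass


@dataclass(frozen=True)
class CrossLinkedPair:
    """Two peptides joined by one K(alpha) <-> Q(beta) isopeptide bond."""

    alpha: Peptide  # Lys donor
    beta: Peptide  # Gln donor
    k_pos: int  # 1-based within alpha
    q_pos: int  # 1-based within beta
    neutral_mass: float

    def __post_init__(self) -> None:
        if self.alpha.sequence[self.k_pos - 1] != "K":
            raise ValueError(f"alpha position {self.k_pos} is not K")
        if self.beta.sequence[self.q_pos - 1] != "Q":
            raise ValueError(f"beta position {self.q_pos} is not Q")
        if self.alpha.modified_at(self.k_pos):
            raise ValueError("cross-linked K carries another modification")
        if self.beta.modified_at(self.q_pos):
            raise ValueError("cross-linked Q carries another modification")

    @property
    def decoy_class(self) -> str:
        n = int(self.alpha.is_decoy) + int(self.beta.is_decoy)
        return ("TT", "TD", "DD")[n]

    @property
    def key(self):
        return (self.alpha.key, self.k_pos, self.beta.key, self.q_pos)


def make_pair(
    alpha: Peptide,
    beta: Peptide,
    k_pos: int,
    q_pos: int,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> CrossLinkedPair:
    """Build a CrossLinkedPair with its neutral mass filled in."""
    mass = peptide_mass(alpha, table) + peptide_mass(beta, table) - table.ammonia_mass
    return CrossLinkedPair(alpha=alpha, beta=beta, k_pos=k_pos, q_pos=q_pos, neutral_mass=mass)


def pair_mass(pair: CrossLinkedPair, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """mass(alpha) + mass(beta) - NH3."""
    return peptide_mass(pair.alpha, table) + peptide_mass(pair.beta, table) - table.ammonia_mass


def mz(neutral_mass: float, charge: int, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """(M + z * proton) / z for a positive ion of charge z >= 1."""
    if charge < 1 or int(charge) != charge:
        raise InvalidChargeError(f"charge must be a positive integer, got {charge!r}")
    return (neutral_mass + charge * table.proton_mass) / charge
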