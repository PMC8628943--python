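"""In silico protease digestion, decoy generation and model-pair design."""
from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Tuple

from .chem import DEFAULT_MASS_TABLE, Peptide, ResidueMassTable

__all__ = [
    "ProteaseRule",
    "DigestParams",
    "TRYPSIN",
    "LYSC",
    "KYTE_DOOLITTLE",
    "digest",
    "cleavage_sites",
    "reverse_protein",
    "mean_hydropathy",
    "design_model_pairs",
    "DECOY_PREFIX",
]

DECOY_PREFIX = "DECOY_"

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}


@dataclass(frozen=True)
class ProteaseRule:
    """Cleave after any residue in ``cleave_after`` unless the next residue
    is in ``suppress_before``."""

    name: str
    cleave_after: FrozenSet[str]
    suppress_before: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")

    def cleaves_at(self, sequence: str, pos: int) -> bool:
        """True if the bond after 1-based position ``pos`` is cleaved."""
        if pos < 1 or pos >= len(sequence):
            return False
        if sequence[pos - 1] not in self.cleave_after:
            return False
        return sequence[pos] not in self.suppress_before


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))
TRYPSIN_NO_SUPPRESSION = ProteaseRule("trypsin/P", frozenset("KR"))
LYSC = ProteaseRule("lysc", frozenset("K"))


@dataclass(frozen=True)
class DigestParams:
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 40

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")


def cleavage_sites(sequence: str, rule: ProteaseRule) -> List[int]:
    """1-based positions after which the protease cleaves."""
    return [i for i in range(1, len(sequence)) if rule.cleaves_at(sequence, i)]


def digest(
    protein_sequence: str,
    protein_id: str,
    rule: ProteaseRule = TRYPSIN,
    params: DigestParams = DigestParams(),
    is_decoy: bool = False,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> List[Peptide]:
    """Fully specific digestion with up to ``max_missed_cleavages`` internal sites.

    Coordinates on the returned peptides are 1-based inclusive positions in
    ``protein_sequence``.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    table.validate(protein_sequence)
    sites = cleavage_sites(protein_sequence, rule)
    # fragment boundaries: [start, end] runs between consecutive cleavage sites
    bounds = [0] + sites + [len(protein_sequence)]
    peptides: List[Peptide] = []
    n_frags = len(bounds) - 1
    for i in range(n_frags):
        for m in range(params.max_missed_cleavages + 1):
            j = i + m
            if j >= n_frags:
                break
            start, end = bounds[i] + 1, bounds[j + 1]
            length = end - start + 1
            if length < params.min_length or length > params.max_length:
                continue
            peptides.append(
                Peptide(
                    sequence=protein_sequence[start - 1 : end],
                    protein_id=protein_id,
                    start=start,
                    end=end,
                    missed_cleavages=m,
                    is_decoy=is_decoy,
                )
            )
    return peptides


def reverse_protein(protein_sequence: str, protein_id: str) -> Tuple[str, str]:
    """Residue-reversed decoy record: (decoy_id, reversed_sequence)."""
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    return DECOY_PREFIX + protein_id, protein_sequence[::-1]


def mean_hydropathy(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy of the sequence."""
    return sum(KYTE_DOOLITTLE[r] for r in sequence) / len(sequence)


def design_model_pairs(
    protein_sequence: str,
    protein_id: str = "protein",
    rule: ProteaseRule = TRYPSIN,
    params: DigestParams = DigestParams(min_length=4, max_length=10),
    max_len: int = 10,
    hydropathy_threshold: float = 0.0,
) -> List[Tuple[Peptide, Peptide]]:
    """Candidate (Lys-donor, Gln-donor) model peptide pairs.

    Selection mirrors the model-pair design criteria: both peptides end in R
    (not K, avoiding side reactions), are short (<= max_len) and hydrophilic
    (mean Kyte-Doolittle hydropathy <= threshold); the Lys donor carries a
    non-C-terminal K and the Gln donor a Q.
    """
    peptides = digest(protein_sequence, protein_id, rule, params)
    eligible = [
        p
        for p in peptides
        if len(p) <= max_len
        and p.sequence.endswith("R")
        and mean_hydropathy(p.sequence) <= hydropathy_threshold
    ]
    k_donors = [p for p in eligible if "K" in p.sequence[:-1]]
    q_donors = [p for p in eligible if "Q" in p.sequence]
    pairs = []
    for a in k_donors:
        for b in q_donors:
            if a.key != b.key:
                pairs.append((a, b))
    return pairs
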