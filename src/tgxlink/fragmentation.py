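"""Theoretical b/y fragment prediction for branched cross-linked pairs.

CID in an ion trap yields predominantly b and y ions, so only those two
series are generated. A fragment whose residue span covers the cross-linked
site carries the entire partner chain as a fixed mass addition
(partner peptide mass - NH3); no cleavage inside the partner chain of a
branched fragment is generated.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List

from .chem import (
    DEFAULT_MASS_TABLE,
    CrossLinkedPair,
    InvalidChargeError,
    Peptide,
    ResidueMassTable,
    mz,
    peptide_mass,
)

__all__ = ["TheoreticalFragment", "predict_fragments", "fragment_conservation_check"]


@dataclass(frozen=True)
class TheoreticalFragment:
    chain: str  # "alpha" | "beta"
    series: str  # "b" | "y"
    index: int  # 1..len(chain)-1
    carries_partner: bool
    charge: int
    neutral_mass: float
    mz: float

    @property
    def position_key(self):
        """Charge-independent identity of the cleavage product."""
        return (self.chain, self.series, self.index)


def _residue_and_mod_masses(p: Peptide, table: ResidueMassTable) -> List[float]:
    masses = [table.residue(r) for r in p.sequence]
    for pos, mod in p.modifications:
        masses[pos - 1] += mod.delta_mass
    return masses


def predict_fragments(
    pair: CrossLinkedPair,
    max_fragment_charge: int = 1,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> List[TheoreticalFragment]:
    """b1..b(n-1) and y1..y(n-1) of both chains at charges 1..max_fragment_charge."""
    if max_fragment_charge < 1:
        raise InvalidChargeError(f"max_fragment_charge must be >= 1, got {max_fragment_charge}")
    out: List[TheoreticalFragment] = []
    chains = (
        ("alpha", pair.alpha, pair.k_pos, pair.beta),
        ("beta", pair.beta, pair.q_pos, pair.alpha),
    )
    for chain_name, chain, site, partner in chains:
        partner_addition = peptide_mass(partner, table) - table.ammonia_mass
        masses = _residue_and_mod_masses(chain, table)
        n = len(masses)
        prefix = [0.0]
        for m in masses:
            prefix.append(prefix[-1] + m)
        for i in range(1, n):
            # b_i spans residues 1..i; y_i spans residues n-i+1..n
            b_neutral = prefix[i]
            b_branched = site <= i
            if b_branched:
                b_neutral += partner_addition
            y_neutral = prefix[n] - prefix[n - i] + table.water_mass
            y_branched = site > n - i
            if y_branched:
                y_neutral += partner_addition
            for z in range(1, max_fragment_charge + 1):
                out.append(
                    TheoreticalFragment(
                        chain=chain_name, series="b", index=i,
                        carries_partner=b_branched, charge=z,
                        neutral_mass=b_neutral, mz=mz(b_neutral, z, table),
                    )
                )
                out.append(
                    TheoreticalFragment(
                        chain=chain_name, series="y", index=i,
                        carries_partner=y_branched, charge=z,
                        neutral_mass=y_neutral, mz=mz(y_neutral, z, table),
                    )
                )
    return out


def fragment_conservation_check(
    pair: CrossLinkedPair,
    fragments: List[TheoreticalFragment],
    tol: float = 1e-4,
) -> bool:
    """b_i + y_(n-i) of each chain must sum to the pair's neutral mass.

    Exactly one of the complementary fragments carries the partner chain, so
    their neutral masses sum to (chain residues + water) + (partner - NH3)
    = pair.neutral_mass.
    """
    by_key = {}
    for f in fragments:
        if f.charge == 1:
            by_key[f.position_key] = f
    for chain_name, chain in (("alpha", pair.alpha), ("beta", pair.beta)):
        n = len(chain)
        for i in range(1, n):
            b = by_key.get((chain_name, "b", i))
            y = by_key.get((chain_name, "y", n - i))
            if b is None or y is None:
                return False
            if b.carries_partner == y.carries_partner:
                return False
            if abs(b.neutral_mass + y.neutral_mass - pair.neutral_mass) > tol:
                return False
    return True
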