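"""Enumeration of cross-linkable peptide pairs and modification expansion."""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    DEFAULT_MASS_TABLE,
    CrossLinkedPair,
    Modification,
    Peptide,
    ResidueMassTable,
    make_pair,
    peptide_mass,
)

__all__ = [
    "SearchParams",
    "crosslinkable_sites",
    "expand_modifications",
    "enumerate_pairs",
]


@dataclass(frozen=True)
class SearchParams:
    precursor_tolerance_ppm: float = 20.0
    fragment_tolerance_da: float = 0.8
    max_crosslinks_per_peptide: int = 1
    fixed_modifications: Tuple[Modification, ...] = ()
    variable_modifications: Tuple[Modification, ...] = ()
    max_variable_mods_per_peptide: int = 2
    allow_cterm_k: bool = False  # count a C-terminal K as a cross-link site

    def __post_init__(self) -> None:
        if self.precursor_tolerance_ppm <= 0 or self.fragment_tolerance_da <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_crosslinks_per_peptide != 1:
            raise ValueError("only max_crosslinks_per_peptide = 1 is supported")


def crosslinkable_sites(
    p: Peptide, allow_cterm_k: bool = False
) -> Tuple[List[int], List[int]]:
    """(K positions, Q positions) eligible for cross-linking, 1-based.

    C-terminal K is excluded by default (an observed cross-linked K blocks
    cleavage, so it appears internal), and so is any K or Q that already
    carries a modification (a deamidated Q has lost the amide that the
    cross-link would consume).
    """
    last = len(p.sequence)
    k_pos = [
        i
        for i in range(1, last + 1)
        if p.sequence[i - 1] == "K"
        and (allow_cterm_k or i != last)
        and not p.modified_at(i)
    ]
    q_pos = [
        i
        for i in range(1, last + 1)
        if p.sequence[i - 1] == "Q" and not p.modified_at(i)
    ]
    return k_pos, q_pos


def expand_modifications(p: Peptide, params: SearchParams) -> List[Peptide]:
    """All modification variants of ``p``.

    Fixed modifications are applied to every matching residue of every
    variant; variable modifications are applied in all combinations of up to
    ``max_variable_mods_per_peptide`` sites (the unmodified variant is always
    included). Residue-targeted only; at most one modification per position.
    """
    fixed: List[Tuple[int, Modification]] = []
    for mod in params.fixed_modifications:
        for i, r in enumerate(p.sequence, start=1):
            if r == mod.target:
                fixed.append((i, mod))
    var_sites: List[Tuple[int, Modification]] = []
    fixed_positions = {pos for pos, _ in fixed}
    for mod in params.variable_modifications:
        for i, r in enumerate(p.sequence, start=1):
            if r == mod.target and i not in fixed_positions:
                var_sites.append((i, mod))

    variants: List[Peptide] = []
    cap = params.max_variable_mods_per_peptide
    for k in range(min(cap, len(var_sites)) + 1):
        for combo in itertools.combinations(var_sites, k):
            positions = [pos for pos, _ in combo]
            if len(set(positions)) != len(positions):
                continue
            mods = tuple(sorted(fixed + list(combo)))
            variants.append(p.with_modifications(mods))
    return variants


def enumerate_pairs(
    peptides: Sequence[Peptide],
    precursor_neutral_mass: float,
    params: SearchParams = SearchParams(),
    beta_peptides: Optional[Sequence[Peptide]] = None,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> List[CrossLinkedPair]:
    """All deduplicated K<->Q pairs whose mass matches the precursor.

    ``peptides`` supplies the Lys donors; ``beta_peptides`` the Gln donors
    (defaults to the same list). A pair is returned when
    ``|pair_mass - M| / M <= precursor_tolerance_ppm * 1e-6``.
    """
    if beta_peptides is None:
        beta_peptides = peptides
    alphas = []
    for p in peptides:
        ks, _ = crosslinkable_sites(p, params.allow_cterm_k)
        if ks:
            alphas.append((p, peptide_mass(p, table), ks))
    betas = []
    for p in beta_peptides:
        _, qs = crosslinkable_sites(p, params.allow_cterm_k)
        if qs:
            betas.append((p, peptide_mass(p, table), qs))
    if not alphas or not betas:
        return []

    beta_masses = np.array([m for _, m, _ in betas])
    order = np.argsort(beta_masses)
    beta_masses = beta_masses[order]

    tol = params.precursor_tolerance_ppm * 1e-6 * precursor_neutral_mass
    out: List[CrossLinkedPair] = []
    seen = set()
    for alpha, a_mass, ks in alphas:
        want = precursor_neutral_mass + table.ammonia_mass - a_mass
        lo = np.searchsorted(beta_masses, want - tol, side="left")
        hi = np.searchsorted(beta_masses, want + tol, side="right")
        for idx in order[lo:hi]:
            beta, b_mass, qs = betas[idx]
            for k in ks:
                for q in qs:
                    pair = make_pair(alpha, beta, k, q, table)
                    if abs(pair.neutral_mass - precursor_neutral_mass) > tol:
                        continue
                    if pair.key in seen:
                        continue
                    seen.add(pair.key)
                    out.append(pair)
    return out
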