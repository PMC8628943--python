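"""End-to-end search: digest -> enumerate -> fragment -> match -> score -> decide.

This is the glue behind the ``search`` CLI subcommand; all substantive logic
lives in the dedicated modules.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .candidates import SearchParams, crosslinkable_sites, enumerate_pairs, expand_modifications
from .chem import (
    CARBAMIDOMETHYL_C,
    DEAMIDATION_Q,
    OXIDATION_M,
    Modification,
    Peptide,
)
from .digestion import (
    TRYPSIN,
    TRYPSIN_NO_SUPPRESSION,
    DigestParams,
    ProteaseRule,
    digest,
    reverse_protein,
)
from .fragmentation import predict_fragments
from .scoring import (
    CrossLinkMatch,
    ScoreThresholds,
    SiteResult,
    Spectrum,
    build_heatmap,
    compute_fdr,
    decide,
    descriptive_score,
    match_peaks,
    overall_score,
    pp2_score,
    pp_score,
    pp_tag_score,
    random_match_probability,
)

__all__ = ["Config", "SearchResult", "run_search", "stable_seed"]

KNOWN_MODIFICATIONS = {
    "carbamidomethyl": CARBAMIDOMETHYL_C,
    "oxidation": OXIDATION_M,
    "deamidation": DEAMIDATION_Q,
}


@dataclass(frozen=True)
class Config:
    """Full search configuration; defaults mirror the reference settings."""

    enzyme: str = "trypsin"
    suppress_proline: bool = True
    max_missed: int = 2
    min_len: int = 6
    max_len: int = 40
    precursor_tol_ppm: float = 20.0
    fragment_tol_da: float = 0.8
    fixed_mods: Tuple[str, ...] = ()
    var_mods: Tuple[str, ...] = ()
    max_var_mods: int = 2
    min_pp: float = 5.0
    min_pp2: float = 5.0
    min_pp_tag: float = 1.3
    overall_threshold: float = 15.0
    min_spectra: int = 2
    decoy: bool = True
    mz_range: Tuple[float, float] = (150.0, 2000.0)
    pp2_draws: int = 10_000
    max_fragment_charge_cap: int = 3
    seed: int = 0

    def protease(self) -> ProteaseRule:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        return TRYPSIN if self.suppress_proline else TRYPSIN_NO_SUPPRESSION

    def modifications(self, names: Sequence[str], variable: bool) -> Tuple[Modification, ...]:
        mods = []
        for name in names:
            if name not in KNOWN_MODIFICATIONS:
                raise ValueError(f"unknown modification {name!r}")
            mods.append(replace(KNOWN_MODIFICATIONS[name], variable=variable))
        return tuple(mods)

    def search_params(self) -> SearchParams:
        return SearchParams(
            precursor_tolerance_ppm=self.precursor_tol_ppm,
            fragment_tolerance_da=self.fragment_tol_da,
            fixed_modifications=self.modifications(self.fixed_mods, variable=False),
            variable_modifications=self.modifications(self.var_mods, variable=True),
            max_variable_mods_per_peptide=self.max_var_mods,
        )

    def thresholds(self) -> ScoreThresholds:
        return ScoreThresholds(
            min_pp=self.min_pp,
            min_pp2=self.min_pp2,
            min_pp_tag=self.min_pp_tag,
            overall_threshold=self.overall_threshold,
            min_spectra=self.min_spectra,
        )

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["mz_range"] = list(self.mz_range)
        d["fixed_mods"] = list(self.fixed_mods)
        d["var_mods"] = list(self.var_mods)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "Config":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fixed_mods", "var_mods"):
            if key in d:
                d[key] = tuple(d[key])
        if "mz_range" in d:
            d["mz_range"] = tuple(d["mz_range"])
        return cls(**d)


def stable_seed(base: int, *parts) -> int:
    """Deterministic 63-bit seed derived from a base seed and string parts."""
    h = hashlib.sha256(("|".join([str(base), *map(str, parts)])).encode()).digest()
    return int.from_bytes(h[:8], "big") >> 1


@dataclass
class SearchResult:
    sites: List[SiteResult]
    proteins: List[Tuple[str, str]]
    config: Config

    @property
    def accepted(self) -> List[SiteResult]:
        return [s for s in self.sites if s.accepted]

    def heatmap(self, protein_id: Optional[str] = None):
        """(q_positions, k_positions, matrix) for one target protein."""
        if protein_id is None:
            protein_id = self.proteins[0][0]
        seq = dict(self.proteins)[protein_id]
        q_positions = [i for i, r in enumerate(seq, start=1) if r == "Q"]
        k_positions = [i for i, r in enumerate(seq, start=1) if r == "K"]
        relevant = [
            s
            for s in self.sites
            if s.alpha_protein == protein_id and s.beta_protein == protein_id
        ]
        return q_positions, k_positions, build_heatmap(q_positions, k_positions, relevant)


def _counts_toward_missed(rule: ProteaseRule, peptide: Peptide, pos: int) -> bool:
    """Whether the K at ``pos`` is an internal cleavage site of the peptide."""
    return rule.cleaves_at(peptide.sequence, pos)


def build_peptide_pools(
    proteins: Sequence[Tuple[str, str]], config: Config
) -> Tuple[List[Peptide], List[Peptide]]:
    """(Lys-donor pool, Gln-donor pool) of modification-expanded peptides.

    Digestion runs with one extra missed cleavage so that a peptide whose
    only excess missed site is the cross-linked K (which the cross-link makes
    uncleavable) is still available as a Lys donor; the budget is enforced
    per role below.
    """
    rule = config.protease()
    params = config.search_params()
    records = [(pid, seq, False) for pid, seq in proteins]
    if config.decoy:
        for pid, seq in proteins:
            did, dseq = reverse_protein(seq, pid)
            records.append((did, dseq, True))
    dparams = DigestParams(
        max_missed_cleavages=config.max_missed + 1,
        min_length=config.min_len,
        max_length=config.max_len,
    )
    alphas: List[Peptide] = []
    betas: List[Peptide] = []
    for pid, seq, is_decoy in records:
        for pep in digest(seq, pid, rule, dparams, is_decoy=is_decoy):
            for var in expand_modifications(pep, params):
                ks, qs = crosslinkable_sites(var, params.allow_cterm_k)
                if qs and var.missed_cleavages <= config.max_missed:
                    betas.append(var)
                eligible_ks = [
                    k
                    for k in ks
                    if var.missed_cleavages - int(_counts_toward_missed(rule, var, k))
                    <= config.max_missed
                ]
                if eligible_ks:
                    alphas.append(var)
    return alphas, betas


def score_match(
    spectrum: Spectrum,
    pair,
    fragments,
    config: Config,
) -> Optional[CrossLinkMatch]:
    """All four scores for one spectrum <-> pair assignment; None if nothing matched."""
    matched = match_peaks(spectrum, fragments, config.fragment_tol_da)
    if not matched:
        return None
    m = CrossLinkMatch(
        pair=pair, scan_id=spectrum.scan_id, matched=matched, n_theoretical=len(fragments)
    )
    m.score = descriptive_score(spectrum, matched)
    m.pp = pp_score(
        len(fragments), len(matched), spectrum, config.fragment_tol_da, config.mz_range
    )
    p_rand = random_match_probability(
        len(spectrum.peaks), config.fragment_tol_da, config.mz_range
    )
    n_positions = len({f.position_key for f in fragments})
    m.pp_tag = pp_tag_score(matched, n_positions, p_rand)
    m.pp2 = pp2_score(
        spectrum,
        matched,
        n_draws_null=config.pp2_draws,
        seed=stable_seed(config.seed, "pp2", spectrum.scan_id, *pair.key),
    )
    return m


def run_search(
    proteins: Sequence[Tuple[str, str]],
    spectra: Sequence[Spectrum],
    config: Config = Config(),
) -> SearchResult:
    """Search all spectra against all cross-linkable peptide pairs of ``proteins``."""
    rule = config.protease()
    params = config.search_params()
    thresholds = config.thresholds()
    alphas, betas = build_peptide_pools(proteins, config)

    # each spectrum is assigned to its single best-scoring candidate site
    best_per_scan: Dict[str, Tuple[Tuple, CrossLinkMatch]] = {}
    for spectrum in spectra:
        if not spectrum.peaks:
            continue
        pairs = enumerate_pairs(
            alphas, spectrum.precursor_neutral_mass, params, beta_peptides=betas
        )
        max_z = max(1, min(spectrum.precursor_charge - 1, config.max_fragment_charge_cap))
        for pair in pairs:
            # enforce the missed-cleavage budget per role (the cross-linked K
            # does not count: the cross-link blocks cleavage there)
            k_excess = int(_counts_toward_missed(rule, pair.alpha, pair.k_pos))
            if pair.alpha.missed_cleavages - k_excess > config.max_missed:
                continue
            if pair.beta.missed_cleavages > config.max_missed:
                continue
            fragments = predict_fragments(pair, max_z)
            m = score_match(spectrum, pair, fragments, config)
            if m is None:
                continue
            site_key = (
                pair.alpha.protein_id,
                pair.alpha.start + pair.k_pos - 1,
                pair.beta.protein_id,
                pair.beta.start + pair.q_pos - 1,
            )
            old = best_per_scan.get(spectrum.scan_id)
            rank = (thresholds.passes_minima(m), m.pp + m.pp2 + m.pp_tag, m.score, site_key)
            if old is None or rank > (
                thresholds.passes_minima(old[1]),
                old[1].pp + old[1].pp2 + old[1].pp_tag,
                old[1].score,
                old[0],
            ):
                best_per_scan[spectrum.scan_id] = (site_key, m)

    sites: Dict[Tuple, SiteResult] = {}
    for _scan, (site_key, m) in sorted(best_per_scan.items()):
        if site_key not in sites:
            a_prot, k_pos, b_prot, q_pos = site_key
            sites[site_key] = SiteResult(
                alpha_protein=a_prot,
                k_protein_pos=k_pos,
                beta_protein=b_prot,
                q_protein_pos=q_pos,
                decoy_class=m.decoy_class,
            )
        sites[site_key].spectra.append(m)

    results = list(sites.values())
    for s in results:
        s.spectra.sort(key=lambda m: -(m.pp + m.pp2 + m.pp_tag))
        s.overall_score = overall_score(s, thresholds)
        s.n_passing = sum(1 for m in s.spectra if thresholds.passes_minima(m))
        s.accepted = decide(
            s, config.overall_threshold, config.min_spectra, thresholds
        )
    for s, q in zip(results, compute_fdr(results)):
        s.q_value = q
    results.sort(key=lambda s: (-s.overall_score, s.site_key))
    return SearchResult(sites=results, proteins=list(proteins), config=config)
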