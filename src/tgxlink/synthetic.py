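"""Seeded CID-like spectrum simulator and benchmark generator.

Collision energy is abstracted into a single ``fragment_coverage`` knob (the
fraction of theoretical b/y fragments that appear as peaks) plus intensity
dispersion; there is no physical fragmentation model. Noise intensities are
drawn from the lower quartile of the signal intensity distribution so
signal-to-noise stays realistic but controllable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import ndtri

from .candidates import crosslinkable_sites
from .chem import CrossLinkedPair, Peptide, make_pair, mz
from .digestion import TRYPSIN, DigestParams, ProteaseRule, digest
from .fragmentation import predict_fragments
from .io import write_mgf
from .scoring import Spectrum

__all__ = [
    "SimParams",
    "simulate_spectrum",
    "generate_benchmark",
    "plantable_sites",
    "random_protein",
    "model_protein_sequence",
    "InsufficientSitesError",
]


class InsufficientSitesError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    fragment_coverage: float = 0.8
    noise_peaks: int = 50
    mz_jitter_sd: float = 0.1
    intensity_log_mean: float = 7.0
    intensity_log_sd: float = 1.0
    mz_range: Tuple[float, float] = (150.0, 2000.0)
    jitter_clip: float = 0.8  # keep jitter inside the matching tolerance
    max_fragment_charge_cap: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragment_coverage <= 1.0:
            raise ValueError("fragment_coverage must be in [0, 1]")
        if self.noise_peaks < 0:
            raise ValueError("noise_peaks must be >= 0")
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be >= 0")


def simulate_spectrum(
    pair: CrossLinkedPair,
    precursor_charge: int,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
    scan_id: str = "sim",
) -> Spectrum:
    """One CID-like spectrum of ``pair``.

    Emits round(coverage * n) of the theoretical fragments with jittered m/z
    and log-normal intensities, plus uniform noise peaks over ``mz_range``
    with lower-quartile intensities.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    max_z = max(1, min(precursor_charge - 1, params.max_fragment_charge_cap))
    fragments = predict_fragments(pair, max_z)
    n_emit = int(round(params.fragment_coverage * len(fragments)))
    peaks: List[Tuple[float, float]] = []
    if n_emit:
        chosen = rng.choice(len(fragments), size=n_emit, replace=False)
        jitter = (
            np.clip(
                rng.normal(0.0, params.mz_jitter_sd, size=n_emit),
                -params.jitter_clip,
                params.jitter_clip,
            )
            if params.mz_jitter_sd > 0
            else np.zeros(n_emit)
        )
        intensities = rng.lognormal(params.intensity_log_mean, params.intensity_log_sd, n_emit)
        for i, frag_idx in enumerate(chosen):
            peaks.append((fragments[frag_idx].mz + jitter[i], float(intensities[i])))
    if params.noise_peaks:
        noise_mz = rng.uniform(*params.mz_range, size=params.noise_peaks)
        quantiles = rng.uniform(1e-9, 0.25, size=params.noise_peaks)
        noise_int = np.exp(params.intensity_log_mean + params.intensity_log_sd * ndtri(quantiles))
        peaks.extend(zip(noise_mz.tolist(), noise_int.tolist()))
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=mz(pair.neutral_mass, precursor_charge),
        precursor_charge=precursor_charge,
        peaks=tuple(sorted(peaks)),
    )


def plantable_sites(
    proteins: Sequence[Tuple[str, str]],
    rule: ProteaseRule = TRYPSIN,
    digest_params: DigestParams = DigestParams(),
    unique_only: bool = True,
) -> List[CrossLinkedPair]:
    """Candidate cross-links between tryptic peptides of the target proteins.

    With ``unique_only`` the Lys donor must have exactly one eligible K and
    the Gln donor exactly one Q, so the planted site is unambiguous; peptides
    from the same protein must not overlap.
    """
    alphas: List[Tuple[Peptide, int]] = []
    betas: List[Tuple[Peptide, int]] = []
    for pid, seq in proteins:
        for pep in digest(seq, pid, rule, digest_params):
            ks, qs = crosslinkable_sites(pep)
            if ks and (not unique_only or len(ks) == 1):
                alphas.append((pep, ks[0]))
            if qs and (not unique_only or len(qs) == 1):
                betas.append((pep, qs[0]))
    pairs: List[CrossLinkedPair] = []
    seen = set()
    for alpha, k in alphas:
        for beta, q in betas:
            if alpha.protein_id == beta.protein_id and not (
                alpha.end < beta.start or beta.end < alpha.start
            ):
                continue
            site = (
                alpha.protein_id,
                alpha.start + k - 1,
                beta.protein_id,
                beta.start + q - 1,
            )
            if site in seen:
                continue
            seen.add(site)
            pairs.append(make_pair(alpha, beta, k, q))
    return pairs


def generate_benchmark(
    proteins: Sequence[Tuple[str, str]],
    n_sites: int,
    spectra_per_site: int,
    params: SimParams,
    mgf_path=None,
    truth_path=None,
    precursor_charge: int = 3,
    rule: ProteaseRule = TRYPSIN,
    digest_params: DigestParams = DigestParams(),
) -> Tuple[List[Spectrum], List[dict]]:
    """Plant ``n_sites`` distinct cross-links and emit spectra plus ground truth.

    Returns (spectra, truth rows); additionally writes an MGF file and a
    ground-truth TSV when paths are given.
    """
    rng = np.random.default_rng(params.seed)
    candidates = plantable_sites(proteins, rule, digest_params)
    if len(candidates) < n_sites:
        raise InsufficientSitesError(
            f"only {len(candidates)} plantable cross-link sites available, "
            f"need {n_sites} ({n_sites - len(candidates)} short)"
        )
    candidates.sort(key=lambda p: p.key)
    chosen_idx = rng.choice(len(candidates), size=n_sites, replace=False)
    spectra: List[Spectrum] = []
    truth: List[dict] = []
    for i, idx in enumerate(chosen_idx):
        pair = candidates[idx]
        scan_ids = []
        for j in range(spectra_per_site):
            scan_id = f"site{i}_rep{j}"
            spectra.append(
                simulate_spectrum(pair, precursor_charge, params, rng=rng, scan_id=scan_id)
            )
            scan_ids.append(scan_id)
        truth.append(
            {
                "alpha_protein": pair.alpha.protein_id,
                "k_protein_pos": pair.alpha.start + pair.k_pos - 1,
                "beta_protein": pair.beta.protein_id,
                "q_protein_pos": pair.beta.start + pair.q_pos - 1,
                "alpha_peptide": pair.alpha.sequence,
                "beta_peptide": pair.beta.sequence,
                "scan_ids": ";".join(scan_ids),
            }
        )
    if mgf_path is not None:
        write_mgf(spectra, mgf_path)
    if truth_path is not None:
        columns = [
            "alpha_protein",
            "k_protein_pos",
            "beta_protein",
            "q_protein_pos",
            "alpha_peptide",
            "beta_peptide",
            "scan_ids",
        ]
        with open(truth_path, "w") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in truth:
                fh.write("\t".join(str(row[c]) for c in columns) + "\n")
    return spectra, truth


_FILLER_ALPHABET = "GASPVTLDNE"  # no K/R/Q, no C/M (keeps masses modification-free)


def random_protein(
    rng: np.random.Generator,
    length: int = 400,
    k_fraction: float = 0.4,
    q_fraction: float = 0.4,
) -> str:
    """Random protein built from tryptic segments ending in R.

    A fraction of segments carries an internal K, another fraction an
    internal Q, so digestion yields plantable cross-link peptide pairs.
    """
    chunks: List[str] = []
    total = 0
    while total < length:
        seg_len = int(rng.integers(5, 10))
        letters = [ _FILLER_ALPHABET[i] for i in rng.integers(0, len(_FILLER_ALPHABET), seg_len) ]
        u = rng.random()
        if u < k_fraction:
            insert = "K"
        elif u < k_fraction + q_fraction:
            insert = "Q"
        else:
            insert = None
        if insert:
            pos = int(rng.integers(1, seg_len))  # never first (avoids R|K edge) nor last
            letters[pos] = insert
        # avoid P directly after the segment-terminal R of the previous chunk
        if chunks and letters[0] == "P":
            letters[0] = "A"
        chunks.append("".join(letters) + "R")
        total += seg_len + 1
    return "".join(chunks)[:length]


def model_protein_sequence() -> str:
    """A collagen-like 1300-residue sequence carrying the model peptides.

    The Lys-donor peptide EGGKGPR occupies residues 893-899 (K896) and the
    Gln-donor peptide SQDGGR occupies residues 1198-1203 (Q1199); everything
    else is a Gly-Pro-Ala filler with no K/R/Q, so tryptic digestion with
    standard length bounds yields exactly the two model peptides.
    """
    seq = list("GPA" * 434)  # 1302 residues of filler
    seq[891] = "R"  # position 892 creates the N-terminal tryptic boundary
    seq[892:899] = "EGGKGPR"
    seq[1196] = "R"
    seq[1197:1203] = "SQDGGR"
    return "".join(seq[:1300])
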