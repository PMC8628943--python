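"""Peak matching, per-spectrum match statistics, site decisions, FDR and heat map.

The four per-spectrum values mirror the semantics of the search engine that
inspired them — a descriptive matched-abundance percentage plus three
-log10-probability statistics driven by matched-ion count (pp), matched-ion
abundance (pp2) and consecutive sequence tags (pp_tag) — but the formulas
here are documented surrogates:

* ``pp``     — exact binomial tail on the number of matched fragments under a
  uniform random-peak null.
* ``pp2``    — Monte-Carlo tail of the matched log-abundance sum over random
  equal-size peak subsets, with a +1 pseudocount; when no null draw reaches
  the observed sum the estimate is refined with a finite-population normal
  tail so that strong matches are not clipped at -log10(1/(n_draws+1)).
* ``pp_tag`` — tail bound n_positions * p_rand**L on the longest run L of
  consecutive matched indices within one (chain, series).

A site's overall score is the sum over spectra passing the per-spectrum
minima of mean(pp, pp2, pp_tag); acceptance additionally requires a minimum
spectral count.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .chem import PROTON_MASS, CrossLinkedPair
from .fragmentation import TheoreticalFragment

__all__ = [
    "Spectrum",
    "FragmentMatch",
    "CrossLinkMatch",
    "SiteResult",
    "ScoreThresholds",
    "match_peaks",
    "descriptive_score",
    "random_match_probability",
    "pp_score",
    "pp2_score",
    "pp_tag_score",
    "overall_score",
    "decide",
    "compute_fdr",
    "build_heatmap",
]

PP_CEILING = 300.0


class UndefinedScoreError(ValueError):
    """Raised when a score is requested for a spectrum with zero total intensity."""


@dataclass(frozen=True)
class Spectrum:
    """One MS2 scan: precursor (m/z, z) and a peak list sorted by m/z."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        mzs = [m for m, _ in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")

    @property
    def precursor_neutral_mass(self) -> float:
        return self.precursor_mz * self.precursor_charge - self.precursor_charge * PROTON_MASS

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass(frozen=True)
class FragmentMatch:
    fragment: TheoreticalFragment
    peak_index: int
    error_da: float
    shared: bool = False  # peak also satisfies another fragment


@dataclass
class CrossLinkMatch:
    pair: CrossLinkedPair
    scan_id: str
    matched: List[FragmentMatch]
    n_theoretical: int
    score: float = 0.0
    pp: float = 0.0
    pp2: float = 0.0
    pp_tag: float = 0.0

    @property
    def decoy_class(self) -> str:
        return self.pair.decoy_class


@dataclass(frozen=True)
class ScoreThresholds:
    min_pp: float = 5.0
    min_pp2: float = 5.0
    min_pp_tag: float = 1.3
    overall_threshold: float = 15.0
    min_spectra: int = 2

    def passes_minima(self, m: CrossLinkMatch) -> bool:
        return m.pp >= self.min_pp and m.pp2 >= self.min_pp2 and m.pp_tag >= self.min_pp_tag


@dataclass
class SiteResult:
    """All spectral evidence for one (Q protein position, K protein position)."""

    alpha_protein: str
    k_protein_pos: int
    beta_protein: str
    q_protein_pos: int
    decoy_class: str
    spectra: List[CrossLinkMatch] = field(default_factory=list)
    overall_score: float = 0.0
    n_passing: int = 0
    accepted: bool = False
    q_value: float = 0.0

    @property
    def site_key(self):
        return (self.alpha_protein, self.k_protein_pos, self.beta_protein, self.q_protein_pos)


def match_peaks(
    spectrum: Spectrum,
    fragments: Sequence[TheoreticalFragment],
    fragment_tolerance_da: float = 0.8,
) -> List[FragmentMatch]:
    """Assign each theoretical fragment to the most intense peak within tolerance.

    Ties are broken by smaller |mass error|, then lower m/z, so matching is
    fully deterministic. A peak may satisfy several fragments; such matches
    are flagged ``shared``.
    """
    if not spectrum.peaks:
        return []
    mzs = spectrum.mz_array
    intens = spectrum.intensity_array
    raw: List[Tuple[TheoreticalFragment, int, float]] = []
    for frag in fragments:
        lo = np.searchsorted(mzs, frag.mz - fragment_tolerance_da, side="left")
        hi = np.searchsorted(mzs, frag.mz + fragment_tolerance_da, side="right")
        if lo == hi:
            continue
        best = min(
            range(lo, hi),
            key=lambda j: (-intens[j], abs(mzs[j] - frag.mz), mzs[j]),
        )
        raw.append((frag, int(best), float(mzs[best] - frag.mz)))
    counts: Dict[int, int] = {}
    for _, j, _ in raw:
        counts[j] = counts.get(j, 0) + 1
    return [
        FragmentMatch(fragment=f, peak_index=j, error_da=e, shared=counts[j] > 1)
        for f, j, e in raw
    ]


def descriptive_score(spectrum: Spectrum, matched: Sequence[FragmentMatch]) -> float:
    """Percentage of total ion intensity carried by matched peaks."""
    total = float(spectrum.intensity_array.sum()) if spectrum.peaks else 0.0
    if total <= 0:
        raise UndefinedScoreError("zero total intensity")
    idx = {m.peak_index for m in matched}
    got = sum(float(spectrum.peaks[j][1]) for j in idx)
    return 100.0 * got / total


def random_match_probability(
    n_peaks: int, tolerance_da: float, mz_range: Tuple[float, float]
) -> float:
    """Chance that a random m/z lands within tolerance of some peak."""
    width = mz_range[1] - mz_range[0]
    if width <= 0:
        raise ValueError("mz_range width must be positive")
    return min(1.0, n_peaks * 2.0 * tolerance_da / width)


def pp_score(
    n_theoretical: int,
    n_matched: int,
    spectrum: Spectrum,
    tolerance_da: float = 0.8,
    mz_range: Tuple[float, float] = (150.0, 2000.0),
) -> float:
    """-log10 P(X >= n_matched), X ~ Binomial(n_theoretical, p_rand)."""
    if n_matched > n_theoretical:
        raise ValueError("n_matched > n_theoretical")
    if n_theoretical == 0 or n_matched == 0:
        return 0.0
    p = random_match_probability(len(spectrum.peaks), tolerance_da, mz_range)
    if p >= 1.0:
        return 0.0
    logsf = stats.binom.logsf(n_matched - 1, n_theoretical, p)
    val = -logsf / math.log(10.0)
    return float(min(max(val, 0.0), PP_CEILING))


def pp2_score(
    spectrum: Spectrum,
    matched: Sequence[FragmentMatch],
    n_draws_null: int = 10_000,
    seed: int = 0,
) -> float:
    """-log10 tail probability of the matched-abundance statistic.

    The statistic is the sum of log1p(intensity) over matched peaks (log
    scale keeps the subset-sum distribution near-normal for heavy-tailed
    intensities). Null model: k peaks drawn uniformly without replacement
    from the spectrum, k = number of distinct matched peaks. Estimated by
    seeded Monte Carlo with a +1 pseudocount; when no draw reaches the
    observed value the probability is refined with a normal tail using the
    exact finite-population mean/variance of the subset sum, so strong
    matches are not clipped at -log10(1/(n_draws+1)).
    """
    idx = sorted({m.peak_index for m in matched})
    k = len(idx)
    n = len(spectrum.peaks)
    if k == 0:
        return 0.0
    intens = np.log1p(spectrum.intensity_array.astype(float))
    observed = float(intens[idx].sum())
    if k >= n:
        return 0.0
    rng = np.random.default_rng(seed)
    # random k-subsets via argpartition of uniform keys
    keys = rng.random((n_draws_null, n))
    subset = np.argpartition(keys, k - 1, axis=1)[:, :k]
    sums = intens[subset].sum(axis=1)
    count = int((sums >= observed).sum())
    p = (count + 1) / (n_draws_null + 1)
    if count == 0:
        mu = intens.mean()
        var = intens.var()
        mean_sum = k * mu
        var_sum = k * var * (n - k) / (n - 1) if n > 1 else 0.0
        if var_sum > 0:
            z = (observed - mean_sum) / math.sqrt(var_sum)
            p = min(p, float(stats.norm.sf(z)))
    p = max(p, 10.0 ** (-PP_CEILING))
    return float(min(-math.log10(p), PP_CEILING))


def _longest_run(indices: Sequence[int]) -> int:
    if not indices:
        return 0
    xs = sorted(set(indices))
    best = run = 1
    for a, b in zip(xs, xs[1:]):
        run = run + 1 if b == a + 1 else 1
        best = max(best, run)
    return best


def pp_tag_score(
    matched: Sequence[FragmentMatch],
    n_positions: int,
    p_rand: float,
) -> float:
    """Sequence-tag statistic: -log10(min(1, n_positions * p_rand**L)).

    L is the longest run of consecutive fragment indices matched within a
    single (chain, series); L <= 1 scores 0.
    """
    groups: Dict[Tuple[str, str], List[int]] = {}
    for m in matched:
        groups.setdefault((m.fragment.chain, m.fragment.series), []).append(m.fragment.index)
    L = max((_longest_run(v) for v in groups.values()), default=0)
    if L <= 1 or p_rand <= 0:
        return 0.0
    p = min(1.0, n_positions * p_rand**L)
    p = max(p, 10.0 ** (-PP_CEILING))
    return float(min(-math.log10(p), PP_CEILING))


def overall_score(site: SiteResult, thresholds: ScoreThresholds = ScoreThresholds()) -> float:
    """Sum of mean(pp, pp2, pp_tag) over spectra passing the per-spectrum minima."""
    total = 0.0
    for m in site.spectra:
        if thresholds.passes_minima(m):
            total += (m.pp + m.pp2 + m.pp_tag) / 3.0
    return total


def decide(
    site: SiteResult,
    overall_threshold: float = 15.0,
    min_spectra: int = 2,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> bool:
    """Accept iff overall score and passing spectral count both meet thresholds."""
    n_passing = sum(1 for m in site.spectra if thresholds.passes_minima(m))
    return site.overall_score >= overall_threshold and n_passing >= min_spectra


def compute_fdr(sites: Sequence[SiteResult]) -> List[float]:
    """q-value per site from TT/TD/DD counts above each overall-score threshold.

    FDR(t) = max(0, TD(t) - DD(t)) / max(1, TT(t)); the q-value of a site is
    the minimum FDR over all thresholds at or below its score, clamped to
    [0, 1].
    """
    if not sites:
        return []
    order = sorted(range(len(sites)), key=lambda i: -sites[i].overall_score)
    tt = td = dd = 0
    fdr_at = [0.0] * len(sites)
    for rank, i in enumerate(order):
        cls = sites[i].decoy_class
        if cls == "TT":
            tt += 1
        elif cls == "TD":
            td += 1
        else:
            dd += 1
        fdr_at[rank] = min(1.0, max(0.0, td - dd) / max(1, tt))
    q = [0.0] * len(sites)
    running = math.inf
    for rank in range(len(order) - 1, -1, -1):
        running = min(running, fdr_at[rank])
        q[order[rank]] = running
    return q


def build_heatmap(
    q_positions: Sequence[int],
    k_positions: Sequence[int],
    sites: Sequence[SiteResult],
) -> np.ndarray:
    """Dense (len(q_positions) x len(k_positions)) matrix of overall scores."""
    qi = {pos: i for i, pos in enumerate(q_positions)}
    ki = {pos: i for i, pos in enumerate(k_positions)}
    matrix = np.zeros((len(q_positions), len(k_positions)))
    for s in sites:
        if s.q_protein_pos in qi and s.k_protein_pos in ki:
            i, j = qi[s.q_protein_pos], ki[s.k_protein_pos]
            matrix[i, j] = max(matrix[i, j], s.overall_score)
    return matrix
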