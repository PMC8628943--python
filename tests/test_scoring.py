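import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tgxlink.fragmentation import TheoreticalFragment, predict_fragments
from tgxlink.scoring import (
    CrossLinkMatch,
    FragmentMatch,
    ScoreThresholds,
    SiteResult,
    Spectrum,
    UndefinedScoreError,
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
from tgxlink.synthetic import SimParams, simulate_spectrum

from .conftest import oracle_binomial_tail


def spectrum_of(peaks, scan_id="s", precursor_mz=651.3133, charge=2):
    return Spectrum(scan_id, precursor_mz, charge, tuple(peaks))


def frag(chain="alpha", series="y", index=1, mz=175.119, charge=1):
    return TheoreticalFragment(
        chain=chain, series=series, index=index, carries_partner=False,
        charge=charge, neutral_mass=(mz - 1.007276) * charge, mz=mz,
    )


def match_of(index, chain="alpha", series="y", peak_index=0):
    return FragmentMatch(fragment=frag(chain, series, index), peak_index=peak_index, error_da=0.0)


class TestMatchPeaks:
    def test_window_arithmetic(self):
        s = spectrum_of([(175.8, 10.0), (176.2, 10.0)])
        (m,) = match_peaks(s, [frag(mz=175.12)], 0.8)
        assert s.peaks[m.peak_index][0] == 175.8

    def test_most_intense_peak_wins(self):
        s = spectrum_of([(175.0, 10.0), (175.3, 100.0)])
        (m,) = match_peaks(s, [frag(mz=175.12)], 0.8)
        assert s.peaks[m.peak_index][1] == 100.0

    def test_txlp_round_trip_all_fragments(self, txlp):
        s = simulate_spectrum(
            txlp, 2, SimParams(fragment_coverage=1.0, noise_peaks=0, mz_jitter_sd=0.0, seed=3)
        )
        frags = predict_fragments(txlp, 1)
        matches = match_peaks(s, frags, 0.8)
        assert len(matches) == 22

    def test_empty_spectrum(self):
        assert match_peaks(spectrum_of([]), [frag()], 0.8) == []

    def test_error_within_tolerance(self, txlp):
        s = simulate_spectrum(
            txlp, 2, SimParams(fragment_coverage=1.0, noise_peaks=20, mz_jitter_sd=0.2, seed=4)
        )
        for m in match_peaks(s, predict_fragments(txlp, 1), 0.8):
            assert abs(m.error_da) <= 0.8


class TestDescriptiveScore:
    def test_worked_example(self):
        peaks = [(100.0, 10.0), (200.0, 20.0), (300.0, 30.0), (400.0, 40.0), (500.0, 100.0)]
        s = spectrum_of(peaks)
        matched = [match_of(1, peak_index=i) for i in (1, 3, 4)]
        assert descriptive_score(s, matched) == pytest.approx(80.0)

    def test_all_matched_is_100(self):
        s = spectrum_of([(100.0, 5.0), (200.0, 5.0)])
        matched = [match_of(1, peak_index=0), match_of(2, peak_index=1)]
        assert descriptive_score(s, matched) == pytest.approx(100.0)

    def test_nothing_matched_is_0(self):
        s = spectrum_of([(100.0, 5.0)])
        assert descriptive_score(s, []) == 0.0

    def test_zero_intensity_is_error(self):
        s = spectrum_of([(100.0, 0.0)])
        with pytest.raises(UndefinedScoreError):
            descriptive_score(s, [])


class TestPpScore:
    def spectrum_with_n_peaks(self, n):
        return spectrum_of([(150.0 + i, 1.0) for i in range(n)])

    def test_zero_matches_scores_zero(self):
        assert pp_score(22, 0, self.spectrum_with_n_peaks(22)) == 0.0

    def test_worked_example_against_exact_tail(self):
        # n_theoretical 22, 22 peaks, tolerance 0.8, range 150-2000, 18 matched
        s = self.spectrum_with_n_peaks(22)
        value = pp_score(22, 18, s, 0.8, (150.0, 2000.0))
        p = 22 * 1.6 / 1850.0
        expected = -math.log10(oracle_binomial_tail(22, 18, p))
        assert value == pytest.approx(expected, rel=1e-6)
        assert value == pytest.approx(27.14, abs=0.01)

    def test_more_noise_decreases_pp(self):
        few = pp_score(22, 10, self.spectrum_with_n_peaks(22))
        many = pp_score(22, 10, self.spectrum_with_n_peaks(44))
        assert many < few

    @given(
        st.integers(1, 12), st.integers(0, 12), st.integers(1, 200),
        st.floats(0.1, 0.9),
    )
    @settings(max_examples=80, deadline=None)
    def test_equivalence_with_exact_enumeration(self, n_theor, n_matched, n_peaks, tol):
        if n_matched > n_theor:
            n_matched = n_theor
        s = self.spectrum_with_n_peaks(n_peaks)
        value = pp_score(n_theor, n_matched, s, tol, (150.0, 2000.0))
        p = random_match_probability(n_peaks, tol, (150.0, 2000.0))
        if n_matched == 0 or p >= 1.0:
            assert value == 0.0
        else:
            expected = min(-math.log10(oracle_binomial_tail(n_theor, n_matched, p)), 300.0)
            assert value == pytest.approx(expected, rel=1e-6, abs=1e-9)


class TestPp2Score:
    def test_no_matches_scores_zero(self):
        s = spectrum_of([(100.0, 5.0)])
        assert pp2_score(s, [], seed=1) == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        peaks = sorted((150 + 10 * i, float(v)) for i, v in enumerate(rng.lognormal(7, 1, 40)))
        s = spectrum_of(peaks)
        matched = [match_of(i + 1, peak_index=i) for i in range(5)]
        a = pp2_score(s, matched, seed=42)
        b = pp2_score(s, matched, seed=42)
        assert a == b
        assert pp2_score(s, matched, seed=43) >= 0.0

    def test_median_peak_scores_about_point_three(self):
        # 101 distinct intensities, matched = the median one: tail prob ~ 0.5
        peaks = [(150.0 + i, float(i + 1)) for i in range(101)]
        s = spectrum_of(peaks)
        matched = [match_of(1, peak_index=50)]
        value = pp2_score(s, matched, n_draws_null=20_000, seed=7)
        assert value == pytest.approx(-math.log10(0.5), abs=0.02)

    def test_top_k_subset_is_maximal(self):
        rng = np.random.default_rng(5)
        peaks = sorted((150 + 7 * i, float(v)) for i, v in enumerate(rng.lognormal(7, 1, 30)))
        s = spectrum_of(peaks)
        order = np.argsort(-s.intensity_array)
        k = 6
        top = [match_of(i + 1, peak_index=int(j)) for i, j in enumerate(order[:k])]
        top_value = pp2_score(s, top, seed=9)
        for start in (5, 10, 24):
            other = [
                match_of(i + 1, peak_index=int(j))
                for i, j in enumerate(order[start : start + k])
            ]
            assert pp2_score(s, other, seed=9) <= top_value


class TestPpTagScore:
    def test_no_matches(self):
        assert pp_tag_score([], 22, 0.02) == 0.0

    def test_single_match_scores_zero(self):
        assert pp_tag_score([match_of(3)], 22, 0.02) == 0.0

    def test_full_y_series_formula(self):
        # y1..y6 matched in one series: L=6, expected -log10(22 * p^6)
        matched = [match_of(i) for i in range(1, 7)]
        p = 0.02
        expected = -math.log10(min(1.0, 22 * p**6))
        assert pp_tag_score(matched, 22, p) == pytest.approx(expected, rel=1e-9)

    def test_nonconsecutive_same_count_scores_lower_or_equal(self):
        consecutive = [match_of(i) for i in (1, 2, 3, 4)]
        scattered = [match_of(i) for i in (1, 3, 5, 7)]
        assert pp_tag_score(scattered, 22, 0.02) <= pp_tag_score(consecutive, 22, 0.02)

    def test_runs_do_not_cross_series(self):
        mixed = [match_of(1, series="y"), match_of(2, series="b"), match_of(3, series="y")]
        assert pp_tag_score(mixed, 22, 0.02) == 0.0


def make_site(score_triples, decoy_class="TT", q_pos=1, k_pos=1):
    site = SiteResult(
        alpha_protein="p", k_protein_pos=k_pos, beta_protein="p",
        q_protein_pos=q_pos, decoy_class=decoy_class,
    )
    for pp, pp2, tag in score_triples:
        site.spectra.append(
            CrossLinkMatch(pair=None, scan_id="s", matched=[], n_theoretical=0,
                           pp=pp, pp2=pp2, pp_tag=tag)
        )
    site.overall_score = overall_score(site)
    return site


class TestOverallAndDecide:
    def test_no_passing_spectra_is_zero(self):
        site = make_site([(4.0, 4.0, 1.0)])
        assert site.overall_score == 0.0

    def test_single_passing_spectrum_mean(self):
        site = make_site([(6.0, 6.0, 6.0)])
        assert site.overall_score == pytest.approx(6.0)

    def test_additivity(self):
        one = make_site([(6.0, 6.0, 6.0)])
        two = make_site([(6.0, 6.0, 6.0), (9.0, 6.0, 3.0)])
        assert two.overall_score > one.overall_score

    def test_accept_high_score_many_spectra(self):
        site = make_site([(5.5, 5.5, 2.2)] * 5)  # overall 22, 5 spectra
        assert site.overall_score == pytest.approx(22.0)
        assert decide(site, 15.0, 2)

    def test_reject_low_score_single_spectrum(self):
        site = make_site([(12.0, 12.0, 6.0)])  # overall 10, 1 spectrum
        assert site.overall_score == pytest.approx(10.0)
        assert not decide(site, 15.0, 2)

    def test_reject_single_spectrum_despite_high_score(self):
        site = make_site([(24.0, 24.0, 18.0)])  # overall 22, 1 spectrum
        assert site.overall_score == pytest.approx(22.0)
        assert not decide(site, 15.0, 2)


class TestFdr:
    def test_plug_in_example(self):
        sites = [make_site([(9.0, 9.0, 9.0)] * 2, "TT", q_pos=i) for i in range(9)]
        sites.append(make_site([(6.0, 6.0, 6.0)], "TD", q_pos=99))
        q = compute_fdr(sites)
        assert q[-1] == pytest.approx(1 / 9)
        assert all(v == 0.0 for v in q[:-1])

    def test_no_decoys_all_zero(self):
        sites = [make_site([(9.0, 9.0, 9.0)], "TT", q_pos=i) for i in range(5)]
        assert compute_fdr(sites) == [0.0] * 5

    def test_all_decoys_clamped_to_one(self):
        sites = [make_site([(9.0, 9.0, 9.0)], "TD", q_pos=i) for i in range(3)]
        assert compute_fdr(sites) == [1.0] * 3

    def test_dd_subtracts_from_td(self):
        sites = [make_site([(9.0, 9.0, 9.0)] * 2, "TT", q_pos=i) for i in range(4)]
        sites.append(make_site([(6.0, 6.0, 6.0)], "TD", q_pos=90))
        q_without_dd = compute_fdr(sites)
        assert q_without_dd[-1] == pytest.approx(1 / 4)
        # a DD below the TD cancels it: max(0, TD - DD) = 0, and the q-value
        # of the TD site drops to 0 via the running minimum over thresholds
        sites.append(make_site([(5.5, 5.5, 5.5)], "DD", q_pos=91))
        q = compute_fdr(sites)
        assert q[-2] == pytest.approx(0.0)
        assert q[-1] == pytest.approx(0.0)

    def test_empty(self):
        assert compute_fdr([]) == []


class TestHeatmap:
    def test_no_identifications_all_zero(self):
        m = build_heatmap([10, 20], [5, 15], [])
        assert m.shape == (2, 2) and not m.any()

    def test_dimensions_match_positions(self):
        m = build_heatmap([1, 2, 3], [4, 5], [])
        assert m.shape == (3, 2)

    def test_scores_land_in_cells(self):
        site = make_site([(6.0, 6.0, 6.0)] * 2, q_pos=20, k_pos=5)
        m = build_heatmap([10, 20], [5, 15], [site])
        assert m[1, 0] == pytest.approx(site.overall_score)
        assert m.sum() == pytest.approx(site.overall_score)
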