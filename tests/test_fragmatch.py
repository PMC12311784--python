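import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histoform.fragmatch import (
    CID_SERIES,
    ECD_SERIES,
    FragmentMatch,
    ScoreConfig,
    SpectrumPeaks,
    intensity_coverage,
    match_fragments,
    ms_score,
    rank_candidates,
    score_proteoform,
    sequence_coverage,
    sequence_validation_pct,
)
from histoform.masscore import (
    FragmentIon,
    Proteoform,
    fragment_ladder,
    mz_from_mass,
)

from conftest import noiseless_spectrum


def fake_match(series, index):
    return FragmentMatch(FragmentIon(series, index, 100.0), 0, 0.0)


class TestMatchFragments:
    def test_exact_dipeptide_match(self):
        p = Proteoform("AG")
        peaks = noiseless_spectrum(p, ("c", "zdot"))
        matches = match_fragments(p, peaks, ("c", "zdot"), tol_ppm=10)
        assert len(matches) == 2
        assert all(m.error_ppm == pytest.approx(0.0, abs=1e-6) for m in matches)

    def test_five_ppm_jitter_within_ten(self):
        p = Proteoform("PEPTIDEKR")
        ladder = fragment_ladder(p, ("c",))
        jittered = tuple(f.neutral_mass * (1 + 5e-6) for f in ladder)
        peaks = SpectrumPeaks(jittered, tuple(1.0 for _ in jittered), "neutral")
        matches = match_fragments(p, peaks, ("c",), tol_ppm=10)
        assert len(matches) == len(ladder)
        assert all(m.error_ppm == pytest.approx(5.0, abs=0.01) for m in matches)

    def test_midway_peak_unmatched(self):
        # two theoretical masses 50 ppm apart; a peak midway is >10 ppm from both
        p = Proteoform("AG")
        c1 = fragment_ladder(p, ("c",))[0].neutral_mass
        peaks = SpectrumPeaks((c1 * (1 + 25e-6),), (1.0,), "neutral")
        assert match_fragments(p, peaks, ("c",), tol_ppm=10) == []

    def test_one_peak_one_fragment(self):
        # a peak equidistant from b2 and y-something picks exactly one partner
        p = Proteoform("GGAGG")
        matches = match_fragments(p, noiseless_spectrum(p, ("b", "y")), ("b", "y"), 10)
        assigned = [m.peak_index for m in matches]
        assert len(assigned) == len(set(assigned))

    def test_mz_mode_charge_enumeration(self):
        p = Proteoform("SGRGKGGKGLGKGGAKR")
        ladder = fragment_ladder(p, ("c",))
        mzs = tuple(sorted(mz_from_mass(f.neutral_mass, 2) for f in ladder))
        peaks = SpectrumPeaks(mzs, tuple(1.0 for _ in mzs), "mz")
        matches = match_fragments(p, peaks, ("c",), tol_ppm=10, max_charge=2)
        assert len(matches) == len(ladder)
        assert all(m.fragment.charge == 2 for m in matches)

    def test_empty_peaks(self):
        p = Proteoform("AG")
        empty = SpectrumPeaks((), (), "neutral")
        assert match_fragments(p, empty, ("c",), 10) == []


class TestSequenceCoverage:
    def test_partial_cleavages(self):
        # matched N-terminal cleavages {1,2,3} on n=10 confirm residues 1-3
        matches = [fake_match("c", i) for i in (1, 2, 3)]
        assert sequence_coverage(matches, 10) == pytest.approx(30.0)

    def test_full_ladder(self):
        matches = [fake_match("c", i) for i in range(1, 10)]
        assert sequence_coverage(matches, 10) == pytest.approx(100.0)

    def test_no_matches(self):
        assert sequence_coverage([], 10) == pytest.approx(0.0)

    def test_single_residue_trivially_confirmed(self):
        # n=1: both termini are evidenced cleavages
        assert sequence_coverage([], 1) == pytest.approx(100.0)

    def test_c_terminal_series_indexing(self):
        # zdot_j evidences cleavage n-j
        matches = [fake_match("zdot", 1)]  # cleavage at 9 on n=10
        assert sequence_coverage(matches, 10) == pytest.approx(10.0)  # residue 10


class TestSVP:
    def test_prefix_plus_suffix(self):
        # confirmed {1,2,3,9,10} -> (3+2)/10
        matches = [fake_match("c", i) for i in (1, 2, 3)] + [
            fake_match("zdot", j) for j in (1, 2)
        ]
        assert sequence_validation_pct(matches, 10) == pytest.approx(50.0)

    def test_all_confirmed(self):
        matches = [fake_match("c", i) for i in range(1, 10)]
        assert sequence_validation_pct(matches, 10) == pytest.approx(100.0)

    def test_interior_only_gives_zero(self):
        # cleavages {4,5} confirm residue 5 only: no terminal run
        matches = [fake_match("c", 4), fake_match("c", 5)]
        assert sequence_validation_pct(matches, 10) == pytest.approx(0.0)
        assert sequence_coverage(matches, 10) == pytest.approx(10.0)


class TestIntensityCoverage:
    def test_direct_quotient(self):
        peaks = SpectrumPeaks((100.0, 200.0, 300.0), (400.0, 350.0, 250.0), "neutral")
        matches = [FragmentMatch(FragmentIon("c", 1, 100.0), 0, 0.0)]
        assert intensity_coverage(matches, peaks) == pytest.approx(40.0)

    def test_all_matched(self):
        peaks = SpectrumPeaks((100.0, 200.0), (1.0, 1.0), "neutral")
        matches = [
            FragmentMatch(FragmentIon("c", 1, 100.0), 0, 0.0),
            FragmentMatch(FragmentIon("c", 2, 200.0), 1, 0.0),
        ]
        assert intensity_coverage(matches, peaks) == pytest.approx(100.0)

    def test_no_double_counting(self):
        peaks = SpectrumPeaks((100.0, 200.0), (600.0, 400.0), "neutral")
        matches = [
            FragmentMatch(FragmentIon("c", 1, 100.0), 0, 0.0),
            FragmentMatch(FragmentIon("zdot", 3, 100.0), 0, 0.0),
        ]
        assert intensity_coverage(matches, peaks) == pytest.approx(60.0)

    def test_zero_intensity_error(self):
        peaks = SpectrumPeaks((100.0,), (0.0,), "neutral")
        with pytest.raises(ValueError):
            intensity_coverage([], peaks)


class TestMsScore:
    @pytest.mark.parametrize(
        "sc,ic,expected",
        [(100.0, 100.0, 100.0), (50.0, 50.0, 25.0), (92.74, 65.77, 60.995)],
    )
    def test_values(self, sc, ic, expected):
        assert ms_score(sc, ic) == pytest.approx(expected, abs=0.005)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            ms_score(150.0, 10.0)

    @given(
        sc=st.floats(min_value=0, max_value=100),
        ic=st.floats(min_value=0, max_value=100),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_min(self, sc, ic):
        assert 0.0 <= ms_score(sc, ic) <= min(sc, ic) + 1e-9


class TestScoreProteoform:
    def test_perfect_spectrum(self):
        p = Proteoform("SGRGKGGKGLGKGGAKR", ((0, "ac"),))
        result = score_proteoform(p, noiseless_spectrum(p), ScoreConfig(("c", "zdot")))
        assert result.sc_pct == pytest.approx(100.0)
        assert result.svp_pct == pytest.approx(100.0)
        assert result.ic_pct == pytest.approx(100.0)
        assert result.ms == pytest.approx(100.0)

    def test_wrong_isomer_scores_lower(self, h4_toy):
        true = Proteoform(h4_toy, ((0, "ac"), (12, "ac")))
        wrong = Proteoform(h4_toy, ((0, "ac"), (16, "ac")))
        peaks = noiseless_spectrum(true)
        cfg = ScoreConfig(("c", "zdot"))
        assert score_proteoform(wrong, peaks, cfg).ms < score_proteoform(true, peaks, cfg).ms

    def test_empty_spectrum_zero_scores(self):
        p = Proteoform("AG")
        result = score_proteoform(p, SpectrumPeaks((), (), "neutral"))
        assert (result.sc_pct, result.svp_pct, result.ic_pct, result.ms) == (0, 0, 0, 0)

    def test_unmatched_peaks_only_dilute_ic(self, h4_toy):
        p = Proteoform(h4_toy)
        base = noiseless_spectrum(p)
        cfg = ScoreConfig(("c", "zdot"))
        r1 = score_proteoform(p, base, cfg)
        with_noise = SpectrumPeaks(
            base.values + (4999.77, 5432.1), base.intensities + (50.0, 50.0), "neutral"
        )
        r2 = score_proteoform(p, with_noise, cfg)
        assert r2.sc_pct == r1.sc_pct
        assert r2.svp_pct == r1.svp_pct
        assert r2.ic_pct < r1.ic_pct


@st.composite
def random_match_sets(draw):
    n = draw(st.integers(min_value=2, max_value=40))
    k = draw(st.integers(min_value=0, max_value=30))
    matches = []
    for _ in range(k):
        series = draw(st.sampled_from(["a", "b", "c", "y", "z", "zdot"]))
        index = draw(st.integers(min_value=1, max_value=n - 1))
        matches.append(fake_match(series, index))
    return n, matches


class TestScoreProperties:
    @given(random_match_sets())
    @settings(max_examples=500, deadline=None)
    def test_svp_le_sc(self, data):
        n, matches = data
        assert sequence_validation_pct(matches, n) <= sequence_coverage(matches, n) + 1e-9

    @given(random_match_sets())
    @settings(max_examples=200, deadline=None)
    def test_scores_in_range(self, data):
        n, matches = data
        sc = sequence_coverage(matches, n)
        svp = sequence_validation_pct(matches, n)
        assert 0 <= svp <= sc <= 100


class TestRanking:
    def test_planted_isomer_top_ranked_noiseless(self, h4_toy):
        true = Proteoform(h4_toy, ((0, "ac"), (12, "ac")))
        candidates = [
            Proteoform(h4_toy, ((0, "ac"), (s, "ac"))) for s in (5, 8, 12, 16)
        ]
        results = rank_candidates(candidates, noiseless_spectrum(true), ScoreConfig(("c", "zdot")))
        assert results[0].proteoform == true

    def test_deterministic_tie_break(self, h4_toy):
        # empty spectrum: all zero scores -> fewer mods, then notation
        candidates = [
            Proteoform(h4_toy, ((0, "ac"), (5, "ac"))),
            Proteoform(h4_toy, ((5, "ac"),)),
            Proteoform(h4_toy, ((0, "ac"),)),
        ]
        results = rank_candidates(candidates, SpectrumPeaks((), (), "neutral"))
        assert len(results[0].proteoform.mods) == 1
        assert results[0].proteoform.notation() < results[1].proteoform.notation()
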