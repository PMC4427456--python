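"""Peak matching, binomial scoring, identification and isoform calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axoprot.pmf import (
    AMBIGUOUS,
    DigestIndex,
    PeakList,
    PmfParams,
    Tolerance,
    assign_isoform,
    diagnostic_peptides,
    identified_ids,
    identify_spot,
    match_peaks,
    replicate_consensus,
    score_match,
)
from axoprot.synthetic import simulate_spectra


def exhaustive_greedy_match(observed, theoretical, tol):
    """Oracle: enumerate all in-tolerance pairs, consume in the stated order."""
    pairs = []
    for i, mz in enumerate(observed):
        for j, t in enumerate(theoretical):
            if abs(mz - t) <= tol.window_da(t):
                pairs.append((abs(mz - t), t, mz, i, j))
    pairs.sort()
    used_i, used_j, out = set(), set(), []
    for _, t, mz, i, j in pairs:
        if i not in used_i and j not in used_j:
            used_i.add(i)
            used_j.add(j)
            out.append((mz, t))
    return sorted(out)


def brute_force_tail_p(n, k, q):
    return sum(math.comb(n, i) * q**i * (1 - q) ** (n - i) for i in range(k, n + 1))


class TestMatchPeaks:
    def test_identical_lists_match_completely_with_zero_delta(self):
        theo = [800.0, 900.0, 1500.0]
        pl = PeakList.from_arrays("s", theo, [1, 1, 1])
        matched = match_peaks(pl, theo, Tolerance(100, "ppm"))
        assert len(matched) == 3
        assert all(m.delta == 0 for m in matched)

    def test_shift_beyond_tolerance_matches_nothing(self):
        theo = np.array([800.0, 900.0, 1500.0])
        shifted = theo * (1 + 200e-6)  # 2x a 100 ppm tolerance
        pl = PeakList.from_arrays("s", shifted, np.ones(3))
        assert match_peaks(pl, theo, Tolerance(100, "ppm")) == []

    def test_one_to_one_no_peak_or_mass_reused(self, rng):
        theo = np.sort(rng.uniform(700, 4000, 40))
        obs = np.sort(rng.choice(theo, 25, replace=False) + rng.normal(0, 0.02, 25))
        matched = match_peaks(PeakList.from_arrays("s", obs, np.ones(25)), theo,
                              Tolerance(0.1, "Da"))
        assert len({m.observed_mz for m in matched}) == len(matched)
        assert len({m.theoretical_mass for m in matched}) == len(matched)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_equal_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        theo = np.sort(rng.uniform(700, 4000, 30))
        obs = np.sort(rng.uniform(700, 4000, 30))
        tol = Tolerance(rng.choice([50.0, 100.0, 500.0]), "ppm")
        got = sorted((m.observed_mz, m.theoretical_mass)
                     for m in match_peaks(PeakList.from_arrays("s", obs, np.ones(30)), theo, tol))
        assert got == pytest.approx(exhaustive_greedy_match(obs, theo, tol))

    def test_empty_observed_list_is_not_an_error(self):
        assert match_peaks(PeakList.from_arrays("s", [], []), [800.0],
                           Tolerance(100, "ppm")) == []

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            Tolerance(-1, "ppm")


class TestScoreMatch:
    def test_zero_matches_scores_zero(self):
        assert score_match(0, 10, 50, 3000.0, 0.1) == 0.0

    def test_all_matched_closed_form(self):
        # p = q^n with q = 0.01, n = 10 -> score exactly 20
        # q = T*2*tol/W = 50*2*0.5/5000 = 0.01
        assert score_match(10, 10, 50, 5000.0, 0.5) == pytest.approx(20.0, abs=1e-9)

    @pytest.mark.parametrize("n,k,tcount,window,tol", [
        (20, 5, 50, 3000.0, 1.5),
        (30, 12, 80, 3300.0, 0.33),
        (15, 4, 40, 1000.0, 0.125),
        (8, 8, 10, 2000.0, 1.0),
    ])
    def test_matches_brute_force_tail_sum(self, n, k, tcount, window, tol):
        q = min(1.0, tcount * 2 * tol / window)
        expect = brute_force_tail_p(n, k, q)
        got_p = 10 ** (-score_match(k, n, tcount, window, tol))
        assert got_p == pytest.approx(expect, rel=1e-9)

    def test_score_strictly_increasing_in_matches(self):
        scores = [score_match(k, 20, 50, 3000.0, 0.15) for k in range(1, 21)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_wider_tolerance_lowers_score(self):
        tight = score_match(8, 20, 50, 3000.0, 0.05)
        loose = score_match(8, 20, 50, 3000.0, 0.5)
        assert tight > loose

    def test_degenerate_dense_database_clamps_to_zero(self):
        assert score_match(10, 10, 10**6, 1000.0, 1.0) == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            score_match(5, 3, 10, 1000.0, 0.1)


class TestIdentifySpot:
    def test_true_protein_ranks_first_with_exact_masses(self, small_proteome):
        proteome, _ = small_proteome
        index = DigestIndex(proteome)
        for pid in sorted(proteome)[:10]:
            peaklist, _ = simulate_spectra(proteome[pid], detection_prob=1.0,
                                           mass_error_ppm_sigma=0.0, n_contaminants=0,
                                           seed=0, spot_id=pid)
            results = identify_spot(peaklist, index)
            assert results[0].protein_id == pid
            assert results[0].identified

    def test_ranks_are_dense_and_sorted(self, small_proteome):
        proteome, _ = small_proteome
        index = DigestIndex(proteome)
        pid = sorted(proteome)[0]
        peaklist, _ = simulate_spectra(proteome[pid], seed=3, spot_id=pid)
        results = identify_spot(peaklist, index)
        assert [r.rank for r in results] == list(range(1, len(proteome) + 1))
        scores = [r.score for r in results]
        assert scores == sorted(scores, reverse=True)

    def test_contaminant_only_spectra_are_never_identified(self, small_proteome):
        proteome, _ = small_proteome
        index = DigestIndex(proteome)
        false_hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            mz = np.sort(rng.uniform(700, 4000, 25))
            results = identify_spot(PeakList.from_arrays("null", mz, np.ones(25)), index)
            false_hits += bool(identified_ids(results))
        assert false_hits == 0

    def test_single_protein_proteome_identifies_itself(self, small_proteome):
        proteome, _ = small_proteome
        pid = sorted(proteome)[0]
        index = DigestIndex({pid: proteome[pid]})
        peaklist, _ = simulate_spectra(proteome[pid], detection_prob=1.0,
                                       mass_error_ppm_sigma=0.0, n_contaminants=0,
                                       seed=0, spot_id=pid)
        results = identify_spot(peaklist, index)
        assert results[0].protein_id == pid and results[0].score > 0

    def test_n_matched_bounded_by_n_observed(self, small_proteome):
        proteome, _ = small_proteome
        index = DigestIndex(proteome)
        pid = sorted(proteome)[1]
        peaklist, _ = simulate_spectra(proteome[pid], seed=9, spot_id=pid)
        for r in identify_spot(peaklist, index):
            assert r.n_matched <= r.n_observed == len(peaklist)


class TestReplicateConsensus:
    def test_two_of_three_accepted_one_of_three_rejected(self):
        runs = {"run1": {"A", "B"}, "run2": {"A", "C"}, "run3": {"A", "B", "D"}}
        accepted = replicate_consensus(runs, min_hits=2)
        assert accepted == {"A", "B"}  # A in 3/3, B in 2/3; C and D only once

    def test_min_hits_above_replicate_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            replicate_consensus({"r1": {"A"}, "r2": {"A"}}, min_hits=3)

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            replicate_consensus({"r1": {"A"}})


class TestDiagnosticPeptides:
    def test_identical_sequences_share_everything(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK"
        ua, ub, shared = diagnostic_peptides(seq, seq)
        assert ua == () and ub == ()
        assert len(shared) > 0

    def test_single_substitution_inside_one_peptide_is_diagnostic(self):
        # one in-window tryptic peptide differs by W->F; all others identical
        a = "GGGGELVISLIVESWAAAGGK" + "LLLLDDDDEEEEFFFFTTTTK"
        b = "GGGGELVISLIVESFAAAGGK" + "LLLLDDDDEEEEFFFFTTTTK"
        ua, ub, shared = diagnostic_peptides(a, b, tolerance=Tolerance(100, "ppm"))
        assert len(ua) >= 1 and len(ub) >= 1
        # masses of the mutated peptide differ by ~W-F, detectable far beyond tolerance
        assert all(abs(x - y) > 1.0 for x in ua for y in ub if abs(x - y) < 100)

    @pytest.mark.parametrize("seed", range(5))
    def test_swap_symmetry(self, seed, small_proteome):
        proteome, truth = small_proteome
        pairs = [(p, t.isoform_partner) for p, t in truth.proteins.items()
                 if t.isoform_partner]
        a_id, b_id = pairs[seed % len(pairs)]
        ua, ub, shared = diagnostic_peptides(proteome[a_id], proteome[b_id])
        ub2, ua2, shared2 = diagnostic_peptides(proteome[b_id], proteome[a_id])
        assert ua == ua2 and ub == ub2 and shared == shared2


class TestAssignIsoform:
    def _pair(self, small_proteome):
        proteome, truth = small_proteome
        a = next(p for p, t in truth.proteins.items() if t.isoform_partner)
        return a, truth.proteins[a].isoform_partner, proteome

    def test_spectrum_with_own_diagnostic_peak_assigned(self, small_proteome):
        a, b, proteome = self._pair(small_proteome)
        peaklist, _ = simulate_spectra(proteome[a], detection_prob=1.0,
                                       mass_error_ppm_sigma=5.0, n_contaminants=0,
                                       seed=1, spot_id="x")
        call = assign_isoform(peaklist, {a: proteome[a], b: proteome[b]})
        assert call.assigned_isoform_id == a
        assert len(call.diagnostic_hits[a]) >= 1
        assert len(call.diagnostic_hits[b]) == 0

    def test_both_isoforms_diagnostics_present_is_ambiguous(self, small_proteome):
        a, b, proteome = self._pair(small_proteome)
        ua, ub, _ = diagnostic_peptides(proteome[a], proteome[b])
        mz = sorted([ua[0], ub[0]])
        call = assign_isoform(PeakList.from_arrays("x", mz, np.ones(len(mz))),
                              {a: proteome[a], b: proteome[b]})
        assert call.assigned_isoform_id == AMBIGUOUS

    def test_shared_peaks_only_is_ambiguous(self, small_proteome):
        a, b, proteome = self._pair(small_proteome)
        _, _, shared = diagnostic_peptides(proteome[a], proteome[b])
        mz = sorted(shared[:6])
        call = assign_isoform(PeakList.from_arrays("x", mz, np.ones(len(mz))),
                              {a: proteome[a], b: proteome[b]})
        assert call.assigned_isoform_id == AMBIGUOUS


class TestPeakListValidation:
    def test_unsorted_peaks_rejected(self):
        with pytest.raises(ValueError):
            PeakList(spot_id="s", peaks=((900.0, 1.0), (800.0, 1.0)))

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(ValueError):
            PeakList(spot_id="s", peaks=((-5.0, 1.0),))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            PeakList(spot_id="s", peaks=((800.0, -1.0),))
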