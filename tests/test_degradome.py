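import numpy as np
import pytest

from mirfam import degradome as dg
from mirfam.records import MirSeqRecord, RunConfig, reverse_complement
from mirfam.synthdata import CANONICAL_MIR166_3P, SimSpec, gen_degradome

MIR = MirSeqRecord(id="mir", sequence=CANONICAL_MIR166_3P)


def perfect_window(mir=MIR):
    return reverse_complement(mir.sequence)


class TestScoreDuplex:
    def test_perfect_reverse_complement_scores_zero(self):
        dup = dg.score_duplex(MIR, perfect_window(), window_start=100)
        assert dup.penalty_score == 0.0
        assert all(state == dg.WC for _, _, state in dup.events)
        assert dup.site_span == (100, 120)

    def test_single_gu_outside_core_costs_half_point(self):
        # miRNA position 15 is A -> target U; replacing the target base
        # with G keeps no pairing... use a miRNA position with G or U
        # so a G:U wobble is possible: position 16 is U (target A->G)
        window = list(perfect_window())
        # miRNA pos 16 (1-based) pairs window index L-16
        mirna_pos = 16
        idx = len(window) - mirna_pos
        assert MIR.sequence[mirna_pos - 1] == "U" and window[idx] == "A"
        window[idx] = "G"
        dup = dg.score_duplex(MIR, "".join(window))
        assert dup.penalty_score == pytest.approx(dg.GU_PENALTY)
        assert dup.state_of(mirna_pos) == dg.GU

    def test_single_gu_in_core_costs_one_point(self):
        window = list(perfect_window())
        mirna_pos = 12  # core region, miRNA base U pairs A
        idx = len(window) - mirna_pos
        assert MIR.sequence[mirna_pos - 1] == "U" and window[idx] == "A"
        window[idx] = "G"
        dup = dg.score_duplex(MIR, "".join(window))
        assert dup.penalty_score == pytest.approx(2 * dg.GU_PENALTY)

    def test_single_mismatch_in_core_costs_two_points(self):
        window = list(perfect_window())
        mirna_pos = 10
        idx = len(window) - mirna_pos
        window[idx] = MIR.sequence[mirna_pos - 1]  # same base cannot pair
        dup = dg.score_duplex(MIR, "".join(window))
        assert dup.penalty_score == pytest.approx(2.0)
        assert dup.state_of(mirna_pos) == dg.MISMATCH

    def test_target_bulge_penalized_per_nucleotide(self):
        window = perfect_window()
        bulged = window[:2] + "A" + window[2:]  # extra nt near miRNA 3' end
        dup = dg.score_duplex(MIR, bulged)
        assert dup.penalty_score <= dg.BULGE_PENALTY * 2
        assert any(state == dg.BULGE_TARGET for _, _, state in dup.events)

    def test_window_length_outside_tolerance_rejected(self):
        with pytest.raises(ValueError, match="window length"):
            dg.score_duplex(MIR, perfect_window()[:10])


class TestFindSliceSite:
    def test_bulge_free_duplex_slice_is_offset_nine_from_three_prime_end(self):
        dup = dg.score_duplex(MIR, perfect_window(), window_start=100)
        # miRNA nt 1 pairs transcript 120, nt 10 pairs 111
        assert dg.find_slice_site(dup) == 111

    def test_unpaired_position_ten_is_an_error(self):
        window = list(perfect_window())
        idx = len(window) - 10
        window[idx] = MIR.sequence[9]  # mismatch opposite nt 10
        dup = dg.score_duplex(MIR, "".join(window))
        with pytest.raises(ValueError, match="position 10"):
            dg.find_slice_site(dup)


class TestClassifyPeak:
    def test_unique_maximum_is_category_zero(self):
        prof = dg.DegradomeProfile("t", np.array([5, 1, 0, 9, 2]))
        assert dg.classify_peak(prof, 4) == 0

    def test_tied_maximum_is_category_one(self):
        prof = dg.DegradomeProfile("t", np.array([9, 1, 0, 9, 2]))
        assert dg.classify_peak(prof, 4) == 1

    def test_above_median_is_category_two(self):
        prof = dg.DegradomeProfile("t", np.array([9, 6, 0, 1, 2]))
        # positives 9,6,1,2 -> median 4; 6 < 9 and 6 > 4
        assert dg.classify_peak(prof, 2) == 2

    def test_single_read_is_category_four(self):
        prof = dg.DegradomeProfile("t", np.array([9, 6, 0, 1, 2]))
        assert dg.classify_peak(prof, 4) == 4

    def test_at_or_below_median_is_category_three(self):
        prof = dg.DegradomeProfile("t", np.array([9, 6, 3, 2, 2]))
        # positives 9,6,3,2,2 -> median 3; site count 3 <= median, > 1
        assert dg.classify_peak(prof, 3) == 3

    def test_zero_reads_is_no_call(self):
        prof = dg.DegradomeProfile("t", np.array([5, 0, 1]))
        with pytest.raises(ValueError, match="no call"):
            dg.classify_peak(prof, 2)

    def test_categories_partition_all_positive_sites(self, np_rng):
        counts = np_rng.poisson(2.0, size=200)
        prof = dg.DegradomeProfile("t", counts)
        for pos in range(1, 201):
            if counts[pos - 1] > 0:
                assert dg.classify_peak(prof, pos) in (0, 1, 2, 3, 4)

    def test_category_invariant_under_position_permutation(self, np_rng):
        counts = np_rng.poisson(3.0, size=50) + 1
        prof = dg.DegradomeProfile("t", counts)
        perm = np_rng.permutation(50)
        shuffled = dg.DegradomeProfile("t", counts[perm])
        for pos in range(1, 51):
            new_pos = int(np.where(perm == pos - 1)[0][0]) + 1
            assert dg.classify_peak(prof, pos) == dg.classify_peak(shuffled, new_pos)


class TestPeakPValue:
    def test_unique_maximum_among_ten_positives(self):
        counts = np.array([10, 1, 2, 3, 4, 5, 6, 7, 8, 9, 0, 0])
        prof = dg.DegradomeProfile("t", counts)
        assert dg.peak_p_value(prof, 1) == pytest.approx(0.1)

    def test_minimum_positive_count_gives_one(self):
        counts = np.array([5, 3, 1, 4, 0])
        prof = dg.DegradomeProfile("t", counts)
        assert dg.peak_p_value(prof, 3) == pytest.approx(1.0)

    def test_matches_direct_enumeration(self, np_rng):
        counts = np_rng.poisson(3.0, size=80)
        prof = dg.DegradomeProfile("t", counts)
        positives = counts[counts > 0]
        for pos in range(1, 81):
            c = counts[pos - 1]
            if c > 0:
                expected = (positives >= c).sum() / len(positives)
                assert dg.peak_p_value(prof, pos) == pytest.approx(expected)

    def test_antitone_in_site_count(self, np_rng):
        counts = np_rng.poisson(4.0, size=60) + 1
        prof = dg.DegradomeProfile("t", counts)
        vals = [(counts[p], dg.peak_p_value(prof, p + 1)) for p in range(60)]
        vals.sort()
        for (c1, p1), (c2, p2) in zip(vals, vals[1:]):
            if c1 < c2:
                assert p1 >= p2


class TestCallTargets:
    def test_planted_perfect_site_with_spike_is_single_category_zero_call(self):
        rng = np.random.default_rng(0)
        L = len(MIR.sequence)
        tx_seq = "".join(rng.choice(list("ACGU"), size=300))
        site_start = 100
        tx_seq = tx_seq[: site_start - 1] + perfect_window() + tx_seq[site_start - 1 + L:]
        t_slice = site_start + L - 10
        counts = rng.poisson(1.0, size=300)
        counts[t_slice - 1] += 60
        tx = MirSeqRecord(id="tx", sequence=tx_seq)
        prof = dg.DegradomeProfile("tx", counts)
        calls = dg.call_targets([MIR], [tx], [prof])
        planted = [c for c in calls if c.t_slice == t_slice]
        assert len(planted) == 1
        assert planted[0].category == 0
        assert planted[0].site_penalty == 0.0

    def test_transcript_without_profile_skipped_with_warning(self, caplog):
        tx = MirSeqRecord(id="lonely", sequence=perfect_window())
        with caplog.at_level("WARNING", logger="mirfam"):
            calls = dg.call_targets([MIR], [tx], [])
        assert calls == []
        assert "lonely" in caplog.text

    def test_planted_battery_recovered_against_truth(self):
        spec = SimSpec(seed=21, n_transcripts=30, n_planted_targets=10,
                       transcript_length=400)
        mirs, tx, prof, truth = gen_degradome(spec)
        calls = dg.call_targets(mirs, tx, prof)
        call_set = {(c.mirna_id, c.transcript_id, c.t_slice) for c in calls}
        truth_set = {(r.mirna_id, r.transcript_id, r.t_slice)
                     for r in truth.itertuples()}
        assert truth_set <= call_set
        for c in calls:
            if (c.mirna_id, c.transcript_id, c.t_slice) in truth_set:
                assert c.category in (0, 1)

    def test_zero_spike_negative_control_recovers_nothing_planted(self):
        spec = SimSpec(seed=22, n_transcripts=20, n_planted_targets=8,
                       transcript_length=400, spike_multiplier=0.0)
        mirs, tx, prof, truth = gen_degradome(spec)
        calls = dg.call_targets(mirs, tx, prof)
        cat01 = [c for c in calls
                 if (c.mirna_id, c.transcript_id, c.t_slice)
                 in {(r.mirna_id, r.transcript_id, r.t_slice) for r in truth.itertuples()}
                 and c.category == 0]
        # without a spike the slice position is just background; it
        # should essentially never be the transcript's unique maximum
        assert len(cat01) <= 1
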