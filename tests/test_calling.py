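import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnam5c import calling
from rnam5c.calling import (
    CallingError,
    bh_adjust,
    binomial_pvalue,
    call_candidates,
    estimate_conversion_error,
    pileup_from_reads,
    replicate_consensus,
)


def exact_tail(n: int, k: int, eps: float) -> float:
    """Independent oracle: term-by-term upper tail in exact rational arithmetic."""
    e = Fraction(*float(eps).as_integer_ratio())
    total = sum(
        math.comb(n, i) * e**i * (1 - e) ** (n - i) for i in range(k, n + 1)
    )
    return float(total)


def pile(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "n", "k"])


class TestSpikeInEstimate:
    def test_pooled_arithmetic(self):
        est = estimate_conversion_error(
            pile([("s", i, "+", 100, 1) for i in range(10)])
        )
        assert est.error == pytest.approx(0.01)
        assert est.conversion_rate == pytest.approx(0.99)
        assert est.total_evidence == 1000

    def test_floor_rule(self):
        est = estimate_conversion_error(pile([("s", 0, "+", 500, 0)]), eps_min=1e-4)
        assert est.error == 1e-4
        assert est.conversion_rate == 1.0

    def test_two_spikeins_pooled(self):
        est = estimate_conversion_error(
            pile([("s1", 0, "+", 600, 3), ("s2", 0, "+", 400, 2)])
        )
        assert est.error == pytest.approx(5 / 1000)

    def test_no_evidence_errors(self):
        with pytest.raises(CallingError):
            estimate_conversion_error(pile([("s", 0, "+", 0, 0)]))


class TestBinomialPvalue:
    def test_all_converted_forced(self):
        assert binomial_pvalue(10, 10, 0.5) == pytest.approx(0.5**10)

    def test_k_zero_is_one(self):
        assert binomial_pvalue(25, 0, 0.01) == 1.0

    def test_against_exact_oracle(self):
        for n, k, eps in [(50, 20, 0.01), (100, 3, 0.005), (500, 12, 0.002),
                          (137, 137, 0.3), (10, 1, 0.5)]:
            p = binomial_pvalue(n, k, eps)
            expected = exact_tail(n, k, eps)
            assert p == pytest.approx(expected, rel=1e-10)

    def test_monotone_in_k(self):
        ps = [binomial_pvalue(60, k, 0.01) for k in range(0, 61)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            binomial_pvalue(5, 6, 0.1)


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        q = bh_adjust([0.001, 0.02, 0.03, 0.5])
        assert q == pytest.approx([0.004, 0.04, 0.04, 0.5])

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_single(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_matches_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(ps)
        _, theirs, _, _ = multipletests(ps, method="fdr_bh")
        assert ours == pytest.approx(theirs, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=30, deadline=None)
    def test_monotone_over_p_ordering(self, ps):
        q = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCallCandidates:
    def test_fails_coverage(self):
        calls = call_candidates(pile([("c", 1, "+", 9, 9)]), eps=0.005)
        assert not calls["passed"].iloc[0]
        assert not calls["pass_coverage"].iloc[0]

    def test_fails_rate(self):
        calls = call_candidates(pile([("c", 1, "+", 100, 15)]), eps=0.005)
        assert not calls["passed"].iloc[0]
        assert not calls["pass_rate"].iloc[0]

    def test_strong_site_passes(self):
        calls = call_candidates(pile([("c", 1, "+", 100, 40)]), eps=0.005)
        row = calls.iloc[0]
        assert row["passed"]
        # q == p for a single tested position; verify against the oracle
        assert row["q_value"] == pytest.approx(exact_tail(100, 40, 0.005), rel=1e-10)

    def test_boundary_coverage_is_inclusive(self):
        calls = call_candidates(pile([("c", 1, "+", 10, 8)]), eps=0.005)
        assert calls["pass_coverage"].iloc[0]

    def test_passing_stable_as_n_grows_at_fixed_rate(self):
        # with k/n fixed at 0.4, growing n only strengthens the evidence
        passed = [
            call_candidates(pile([("c", 1, "+", n, int(0.4 * n))]), eps=0.005)
            ["passed"].iloc[0]
            for n in range(10, 200, 5)
        ]
        first_pass = passed.index(True)
        assert all(passed[first_pass:])


class TestReplicateConsensus:
    def _calls(self, passing: bool):
        n, k = (100, 50) if passing else (100, 5)
        return call_candidates(pile([("c", 7, "+", n, k)]), eps=0.005)

    def test_all_pass_is_consensus(self):
        cons = replicate_consensus([self._calls(True)] * 3)
        assert len(cons) == 1
        assert cons["mean_rate"].iloc[0] == pytest.approx(0.5)

    def test_one_fail_drops(self):
        cons = replicate_consensus(
            [self._calls(True), self._calls(True), self._calls(False)]
        )
        assert len(cons) == 0

    def test_absent_site_drops(self):
        other_pos = call_candidates(pile([("c", 99, "+", 100, 50)]), eps=0.005)
        cons = replicate_consensus([self._calls(True), self._calls(True), other_pos])
        assert len(cons) == 0

    def test_replicate_count_mismatch(self):
        with pytest.raises(CallingError):
            replicate_consensus([self._calls(True)] * 2, n_reps=3)


class TestPileupFromReads:
    REF = {"tx1": "AAAAACAAAAAAAAAChAAAC".replace("h", "A")}

    def _reads(self, seq, start=0, orientation="fwd", q=40):
        return pd.DataFrame(
            [("tx1", start, orientation, seq, chr(q + 33) * len(seq))],
            columns=["transcript_id", "start", "orientation", "seq", "qual"],
        )

    def test_trim_fwd_masks_5prime(self):
        # C at read offset 5 lies inside the 10-base forward trim window
        reads = self._reads("AAAAACAAAAAAAAAC")
        pileup = pileup_from_reads(reads, self.REF, trim_fwd=10, trim_rev=7, q_min=35)
        assert 5 not in set(pileup["pos"])
        assert set(pileup["pos"]) == {15}

    def test_rev_read_trims_rightmost(self):
        reads = self._reads("AAAAACAAAAAAAAAC", orientation="rev")
        pileup = pileup_from_reads(reads, self.REF, trim_fwd=10, trim_rev=7, q_min=35)
        # 5' end of a reverse read is its rightmost base; offset 15 is within 7
        assert set(pileup["pos"]) == {5}

    def test_low_quality_excluded(self):
        reads = self._reads("AAAAAAAAAAAAAAAC", q=34)
        pileup = pileup_from_reads(reads, self.REF, q_min=35)
        assert len(pileup) == 0

    def test_twenty_reads_all_c(self):
        reads = pd.concat([self._reads("AAAAAAAAAAAAAAAC")] * 20, ignore_index=True)
        pileup = pileup_from_reads(reads, self.REF, q_min=35)
        row = pileup.iloc[0]
        assert (row["pos"], row["n"], row["k"]) == (15, 20, 20)

    def test_t_counts_as_converted(self):
        reads = self._reads("AAAAAAAAAAAAAAAT")
        pileup = pileup_from_reads(reads, self.REF, q_min=35)
        row = pileup.iloc[0]
        assert (row["n"], row["k"]) == (1, 0)

    def test_read_beyond_transcript_errors(self):
        reads = self._reads("A" * 30, start=0)
        with pytest.raises(CallingError):
            pileup_from_reads(reads, self.REF)


class TestSimulatedRoundTrip:
    def test_reads_agree_with_truth(self, plain_st):
        from rnam5c import synthetic_data

        truth = synthetic_data.plant_methylation(plain_st, "ESC")
        reads = synthetic_data.simulate_reads(plain_st, truth, "ESC", 1)
        refs = plain_st.transcript_sequences()
        pileup = pileup_from_reads(reads, refs, trim_fwd=0, trim_rev=0, q_min=20)
        level = {(s.transcript_id, s.transcript_pos): s.level for s in truth}
        strong = pileup[pileup["n"] >= 30]
        rates = strong["k"] / strong["n"]
        planted = np.array(
            [level.get((r.chrom, r.pos), 0.0) for r in strong.itertuples()]
        )
        # pooled non-conversion at unmethylated Cs stays near epsilon
        null_rate = rates[planted == 0].mean()
        assert null_rate < 0.03
        high = planted >= 0.8
        if high.any():
            assert rates[high].mean() > 0.6
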