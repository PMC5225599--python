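from math import comb

import numpy as np
import pytest
from scipy import stats

from rnam5c.core_io import GenomicSite, TranscriptModel
from rnam5c.positional import (
    PositionalError,
    all_transcript_cs,
    assign_segment,
    average_segment_lengths,
    enrichment_table,
    metagene_profile,
    odds_ratio_ci,
    sample_random_cs,
    segment_enrichment,
)


def fisher_oracle(a, b, c, d):
    """Exhaustive enumeration of tables with the observed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def seq_model(utr5, cds, utr3, tid="t1", chrom="chr1", strand="+", offset=0):
    L = utr5 + cds + utr3
    return TranscriptModel(
        transcript_id=tid, gene_id=tid, chrom=chrom, strand=strand,
        exons=[(offset, offset + L)],
        cds_start=offset + utr5, cds_end=offset + utr5 + cds,
    )


class TestAssignSegment:
    def test_unique_cds(self):
        m = seq_model(50, 150, 100)
        asn = assign_segment(GenomicSite("chr1", 60, "+"), [m])
        assert asn.feature == "cds" and asn.transcript_id == "t1"

    def test_exonic_beats_intronic(self):
        x = TranscriptModel("x", "gx", "chr1", "+", [(0, 100)],
                            cds_start=10, cds_end=90)
        y = TranscriptModel("y", "gy", "chr1", "+", [(0, 40), (80, 200)],
                            cds_start=10, cds_end=150)
        asn = assign_segment(GenomicSite("chr1", 50, "+"), [x, y])
        assert asn.feature == "cds" and asn.transcript_id == "x"

    def test_outside_genes_non_annotated(self):
        m = seq_model(50, 150, 100)
        asn = assign_segment(GenomicSite("chr1", 5000, "+"), [m])
        assert asn.feature == "non_annotated" and asn.transcript_id is None

    def test_intron(self):
        m = TranscriptModel("t", "g", "chr1", "+", [(0, 40), (80, 200)],
                            cds_start=10, cds_end=150)
        assert assign_segment(GenomicSite("chr1", 50, "+"), [m]).feature == "intron"

    def test_longest_cds_wins(self):
        a = seq_model(10, 60, 30, tid="a")
        b = seq_model(10, 90, 3, tid="b")
        asn = assign_segment(GenomicSite("chr1", 30, "+"), [a, b])
        assert asn.transcript_id == "b"

    def test_strand_mismatch_ignored(self):
        m = seq_model(50, 150, 100)
        asn = assign_segment(GenomicSite("chr1", 60, "-"), [m])
        assert asn.feature == "non_annotated"


class TestMetagene:
    def _models(self):
        # average segment lengths (200, 1000, 800), total 2000
        return [seq_model(200, 1000, 800, tid="t1"),
                seq_model(200, 1000, 800, tid="t2", offset=3000)]

    def _assign(self, models, gpos):
        return [assign_segment(GenomicSite("chr1", p, "+"), models) for p in gpos]

    def test_cds_start_lands_in_bin_10(self):
        models = self._models()
        avg = average_segment_lengths(models)
        assert avg == {"utr5": 200.0, "cds": 1000.0, "utr3": 800.0}
        profile = metagene_profile(self._assign(models, [200]), models)
        assert profile.counts[10] == 1  # 200/2000 -> bin 10

    def test_transcript_start_bin_0(self):
        models = self._models()
        profile = metagene_profile(self._assign(models, [0]), models)
        assert profile.counts[0] == 1

    def test_last_utr3_base_clamps_to_99(self):
        models = self._models()
        profile = metagene_profile(self._assign(models, [1999]), models)
        assert profile.counts[99] == 1

    def test_percent_sums_to_100(self):
        models = self._models()
        rng = np.random.default_rng(0)
        gpos = rng.integers(0, 2000, 200)
        profile = metagene_profile(self._assign(models, gpos), models)
        assert profile.percent.sum() == pytest.approx(100.0)
        assert profile.boundaries == (10.0, 60.0)

    def test_non_mrna_site_rejected(self):
        models = self._models()
        asn = self._assign(models, [2500])  # intergenic
        with pytest.raises(PositionalError):
            metagene_profile(asn, models)


class TestRandomCs:
    def test_full_universe_when_n_equals_total(self, plain_st):
        models = plain_st.models[:3]
        universe = all_transcript_cs(models, plain_st.genome)
        sample = sample_random_cs(models, plain_st.genome, len(universe), 1)
        assert {s.key() for s in sample} == {s.key() for s in universe}

    def test_deterministic_under_seed(self, plain_st):
        models = plain_st.models[:3]
        s1 = sample_random_cs(models, plain_st.genome, 10, 42)
        s2 = sample_random_cs(models, plain_st.genome, 10, 42)
        assert [s.key() for s in s1] == [s.key() for s in s2]

    def test_insufficient_cs_errors(self, plain_st):
        models = plain_st.models[:1]
        total = len(all_transcript_cs(models, plain_st.genome))
        with pytest.raises(PositionalError):
            sample_random_cs(models, plain_st.genome, total + 1, 0)

    def test_sampling_frequency_uniform(self, plain_st):
        models = plain_st.models[:1]
        universe = all_transcript_cs(models, plain_st.genome)
        n_u = len(universe)
        draws, m = 3000, 5
        counts = {}
        for seed in range(draws):
            for s in sample_random_cs(models, plain_st.genome, m, seed):
                counts[s.key()] = counts.get(s.key(), 0) + 1
        p = m / n_u
        expected = draws * p
        sd = np.sqrt(draws * p * (1 - p))
        observed = np.array([counts.get(s.key(), 0) for s in universe])
        assert np.all(np.abs(observed - expected) < 5 * sd)

    def test_random_profile_flat(self, plain_st):
        coding = [m for m in plain_st.models if m.is_coding]
        n = len(all_transcript_cs(coding, plain_st.genome)) * 3 // 4
        sample = sample_random_cs(coding, plain_st.genome, n, 7)
        asn = [assign_segment(s, plain_st.models) for s in sample]
        mrna = [a for a in asn if a.feature in ("utr5", "cds", "utr3")]
        profile = metagene_profile(mrna, coding)
        chi2 = ((profile.counts - profile.n_sites / 100) ** 2
                / (profile.n_sites / 100)).sum()
        p = stats.chi2.sf(chi2, 99)
        assert p > 1e-3


class TestEnrichment:
    def test_symmetric_table(self):
        orr, _ = odds_ratio_ci(5, 95, 5, 95)
        assert orr == 1.0
        _, p = stats.fisher_exact([[5, 95], [5, 95]])
        assert p == 1.0

    def test_small_table_matches_enumeration(self):
        a, b, c, d = 3, 1, 1, 3
        _, p = stats.fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_tables_vs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            cells = rng.multinomial(int(rng.integers(4, 61)), [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7)

    def test_haldane_correction_on_zero_cell(self):
        orr, ci = odds_ratio_ci(5, 0, 3, 10)
        expected = (5.5 * 10.5) / (0.5 * 3.5)
        assert orr == pytest.approx(expected)
        assert ci[0] < orr < ci[1]

    def test_planted_aug_window_enrichment(self):
        # all m5Cs inside AUG +/- 25 on a long-CDS transcript set
        models = [seq_model(150, 600, 150, tid=f"t{i}", offset=i * 2000)
                  for i in range(5)]
        genome = {"chr1": ""}
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 10 * 2000))
        genome["chr1"] = seq
        m5c = []
        for m in models:
            tseq = m.spliced_sequence(genome)
            aug = m.segments()["cds"][0]
            for t in range(aug - 25, aug + 26):
                if tseq[t] == "C":
                    m5c.append(GenomicSite("chr1", m.transcript_to_genomic(t), "+",
                                           transcript_id=m.transcript_id,
                                           transcript_pos=t))
        res = {r.region: r for r in enrichment_table(m5c, models, genome)}
        assert res["aug25"].odds_ratio > 1
        assert res["aug25"].p_value < 0.01
        assert res["cds"].odds_ratio < 1

    def test_empty_background_errors(self):
        models = [seq_model(20, 30, 20)]
        with pytest.raises(PositionalError):
            segment_enrichment([], models, {"chr1": "A" * 100}, "cds")
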