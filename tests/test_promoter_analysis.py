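import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonkit import promoter_analysis as pa


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact P by exact hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return Fraction(comb(c1, k) * comb(n - c1, r1 - k), comb(n, r1))

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        if pmf(k) <= p_obs:
            total += pmf(k)
    return float(total)


def tss(pos, strand="+", category="primary", gene="g", chrom="chr"):
    return pa.TSSRecord(chrom=chrom, position=pos, strand=strand,
                        category=category, gene_id=gene)


class TestFilterPrimary:
    def test_mixed_categories(self):
        records = [tss(100, category="primary", gene="a"),
                   tss(200, category="secondary", gene="b"),
                   tss(300, category="primary", gene="c")]
        kept = pa.filter_primary_tss(records)
        assert [r.gene_id for r in kept] == ["a", "c"]

    def test_empty(self):
        assert pa.filter_primary_tss([]) == []

    def test_fixture_count_matches_truth(self, fixtures):
        primary = pa.filter_primary_tss(fixtures.tss)
        assert len(primary) == len(fixtures.promoter_truth)


class TestExtractWindows:
    genome = {"chr": "ACGT" * 50}

    def test_window_lengths(self):
        (w10,) = pa.extract_windows([tss(100)], self.genome, -20, 0)
        assert len(w10.sequence) == 21
        (w35,) = pa.extract_windows([tss(100)], self.genome, -40, -25)
        assert len(w35.sequence) == 16

    def test_plus_strand_content(self):
        genome = {"chr": "AAAATTTTGGGGCCCC"}
        (w,) = pa.extract_windows([tss(8)], genome, -3, 0)
        assert w.sequence == "TTTT"  # 1-based positions 5..8

    def test_minus_strand_reverse_complement(self):
        genome = {"chr": "AAAATTTTGGGGCCCC"}
        (w,) = pa.extract_windows([tss(9, strand="-")], genome, -3, 0)
        # genomic positions 9..12 = GGGG; window reads its RC
        assert w.sequence == "CCCC"

    def test_strand_symmetry(self, fixtures):
        # planted motifs are recovered identically regardless of strand
        primary = pa.filter_primary_tss(fixtures.tss)
        windows = pa.extract_windows(primary, fixtures.genome)
        strands = {w.tss.strand for w in windows}
        assert strands == {"+", "-"}

    def test_out_of_contig_skipped(self, caplog):
        windows = pa.extract_windows([tss(5)], self.genome, -20, 0)
        assert windows == []

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="contig"):
            pa.extract_windows([tss(100, chrom="nope")], self.genome)


class TestScanMotif:
    def _window(self, seq, from_off=-20):
        record = tss(1000)
        return pa.PromoterWindow(tss=record, sequence=seq, from_off=from_off,
                                 to_off=from_off + len(seq) - 1)

    def test_literal_match_anchored(self):
        seq = "C" * 8 + "TACGGT" + "C" * 7
        (site,) = pa.scan_motif([self._window(seq)])
        assert site.motif == "TACGGT"
        assert site.anchor_off == -12

    def test_no_match_dropped(self):
        assert pa.scan_motif([self._window("C" * 21)]) == []

    def test_anchor_too_close_to_edge_skipped(self):
        seq = "TACGGT" + "C" * 15
        assert pa.scan_motif([self._window(seq)]) == []

    def test_pwm_pvalue_matches_enumeration(self):
        # PWM concentrated on TACGGT with some tolerance
        pwm = np.full((4, 6), 0.05)
        for j, base in enumerate("TACGGT"):
            pwm["ACGT".index(base), j] = 0.85
        seq = "C" * 8 + "TACGGT" + "C" * 7
        (site,) = pa.scan_motif([self._window(seq)], pwm=pwm, p_max=0.5)
        # oracle: exhaustive enumeration of all 4^6 hexamers
        logodds = np.log(pwm) - np.log(0.25)
        def score(h):
            return sum(logodds["ACGT".index(b), j] for j, b in enumerate(h))
        best = score("TACGGT")
        count = sum(1 for h in itertools.product("ACGT", repeat=6)
                    if score(h) >= best - 1e-12)
        assert site.p_value == pytest.approx(count / 4096, abs=1e-12)

    def test_malformed_pwm_rejected(self):
        with pytest.raises(ValueError):
            pa.scan_motif([], pwm=np.ones((4, 5)))

    def test_fixture_round_trip(self, fixtures):
        primary = pa.filter_primary_tss(fixtures.tss)
        windows = pa.extract_windows(primary, fixtures.genome)
        sites = pa.scan_motif(windows)
        truth = fixtures.promoter_truth.set_index("gene_id")
        planted = truth[truth["motif_planted"]]
        got = {s.window.tss.gene_id: s for s in sites}
        assert set(got) == set(planted.index)
        for gene_id, row in planted.iterrows():
            site = got[gene_id]
            assert site.anchor_off == -12
            assert site.gg_class == row["gg_class"]
            assert site.upstream_dinucleotide == row["gg_pair"]


class TestClassifyGG:
    def _site(self, pair, anchor_base="T"):
        w = pa.PromoterWindow(tss=tss(1000), sequence="x", from_off=-20,
                              to_off=0)
        return pa.PromoterSite(window=w, anchor_off=-12,
                               motif=anchor_base + "AAAAT",
                               gg_class={2: "GG", 1: "G", 0: "noG"}[
                                   pair.count("G")],
                               upstream_dinucleotide=pair,
                               base_at_minus12=anchor_base)

    def test_classes(self):
        counts = pa.classify_gg([self._site("GG"), self._site("GA"),
                                 self._site("AG"), self._site("AT")])
        assert counts["classes"] == {"GG": 1, "G": 2, "noG": 1}

    def test_sum_equals_n_sites(self):
        sites = [self._site(p) for p in ("GG", "CG", "AA", "GG", "TC")]
        counts = pa.classify_gg(sites)["classes"]
        assert sum(counts.values()) == len(sites)

    def test_planted_rate_binomial(self):
        # binomial oracle: with rate 0.5 and n=1000, 3 sigma ~ 47
        rng = np.random.default_rng(0)
        pairs = ["GG" if rng.random() < 0.5 else "AT" for _ in range(1000)]
        counts = pa.classify_gg([self._site(p) for p in pairs])["classes"]
        assert abs(counts["GG"] - 500) < 3 * np.sqrt(1000 * 0.25)


class TestGenomeGGFrequency:
    def test_ggg_overlapping(self):
        assert pa.genome_gg_frequency("GGG") == 1.0

    def test_no_gg(self):
        assert pa.genome_gg_frequency("ATAT") == 0.0

    def test_hand_count(self):
        assert pa.genome_gg_frequency("GGAT") == pytest.approx(1 / 3)

    def test_multi_contig(self):
        freq = pa.genome_gg_frequency({"a": "GGG", "b": "ATAT"})
        assert freq == pytest.approx(2 / 5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pa.genome_gg_frequency("")

    def test_uniform_genome_near_one_sixteenth(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        freq = pa.genome_gg_frequency(seq)
        sigma = np.sqrt((1 / 16) * (15 / 16) / 100_000)
        assert abs(freq - 1 / 16) < 4 * sigma


class TestExpectedGG:
    def test_worked_example(self):
        raw, rounded = pa.expected_gg_sites(0.114, 954)
        assert raw == pytest.approx(108.756)
        assert rounded == 109

    def test_zero_frequency(self):
        assert pa.expected_gg_sites(0.0, 100) == (0.0, 0)

    def test_unit_frequency(self):
        assert pa.expected_gg_sites(1.0, 10) == (10.0, 10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pa.expected_gg_sites(1.5, 10)
        with pytest.raises(ValueError):
            pa.expected_gg_sites(0.5, -1)


class TestFisher:
    def test_balanced_table(self):
        assert pa.fisher_gg_enrichment(10, 10, 10, 10) == pytest.approx(1.0)

    def test_extreme_table_derived(self):
        # all 5 successes in one margin: 2 / C(10,5) = 2/252
        assert pa.fisher_gg_enrichment(5, 0, 0, 5) == pytest.approx(
            2 / 252, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pa.fisher_gg_enrichment(0, 0, 0, 0)

    @settings(max_examples=60, deadline=None)
    @given(a=st.integers(0, 25), b=st.integers(0, 25),
           c=st.integers(0, 25), d=st.integers(0, 25))
    def test_matches_hypergeometric_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert pa.fisher_gg_enrichment(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12)


class TestEnrichmentReport:
    def test_fixture_report(self, fixtures):
        primary = pa.filter_primary_tss(fixtures.tss)
        truth = fixtures.promoter_truth
        dep = {g for g, c in zip(truth["gene_id"], truth["class"])
               if c == "dependent"}
        dep_recs = [r for r in primary if r.gene_id in dep]
        ind_recs = [r for r in primary if r.gene_id not in dep]
        sites_dep = pa.scan_motif(pa.extract_windows(dep_recs,
                                                     fixtures.genome))
        sites_ind = pa.scan_motif(pa.extract_windows(ind_recs,
                                                     fixtures.genome))
        result = pa.enrichment_report(sites_dep, sites_ind, fixtures.genome)
        assert sum(result.counts.values()) == result.n_sites
        assert result.expected_gg == pytest.approx(
            result.genome_gg_frequency * result.n_sites)
        assert 0 < result.fisher_p <= 1
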