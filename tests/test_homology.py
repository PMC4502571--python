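"""Local alignment and the annotation / screening / read-mapping filters."""

import numpy as np
import pytest

from lgtscan import OrfRecord, PipelineConfig
from lgtscan.homology import (ScoringParams, annotate_function,
                              classify_read_spans, local_align,
                              map_reads_to_contigs, mge_homology_filter,
                              screen_equal_evalue_out_of_class)

from conftest import make_hit


def gotoh_local_score(a: str, b: str, p: ScoringParams) -> float:
    """Independent affine-gap local alignment DP (first gap column costs
    gap_open, later columns gap_extend), written against the same gap
    convention as the package aligner."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + p.gap_open,
                          E[i][j - 1] + p.gap_extend)
            F[i][j] = max(H[i - 1][j] + p.gap_open,
                          F[i - 1][j] + p.gap_extend)
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlign:
    def test_self_alignment(self):
        hit = local_align("A" * 100, "A" * 100)
        assert hit.pct_identity == 100.0 and hit.aln_len == 100
        assert hit.q_start == 1 and hit.q_end == 100

    def test_hand_scored_dp(self):
        # 4 matches at +2 each
        hit = local_align("ACGT", "ACGT")
        expected = gotoh_local_score("ACGT", "ACGT", ScoringParams())
        assert expected == 8.0
        assert hit.bitscore == pytest.approx(
            (0.32 * 8 - np.log(0.13)) / np.log(2))

    def test_reverse_complement_orientation(self):
        from lgtscan.composition import reverse_complement
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        fwd = local_align(seq, seq)
        rev = local_align(reverse_complement(seq), seq)
        assert rev.pct_identity == 100.0
        assert rev.aln_len == fwd.aln_len

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_matches_independent_dp_oracle(self):
        """Optimal score equals a hand-written Gotoh DP on random short
        pairs (protein mode isolates a single orientation)."""
        rng = np.random.default_rng(42)
        params = ScoringParams()
        for _ in range(60):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4,
                                                        rng.integers(1, 13)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4,
                                                        rng.integers(1, 13)))
            expected = gotoh_local_score(a, b, params)
            hit = local_align(a, b, scoring=params, nucleotide=False)
            got = 0.0 if hit is None else \
                (hit.bitscore * np.log(2) + np.log(0.13)) / 0.32
            assert got == pytest.approx(expected, abs=1e-6)


class TestAnnotateFunction:
    def orf(self, aa=300):
        return OrfRecord("o1", "c1", 1, 3 * (aa + 2), "+", "M" * aa)

    def test_length_ratio_rule(self):
        # reference 400 aa vs query 300 aa: 400 > 1.2 * 300 -> rejected
        hit = make_hit(query_id="o1", aln_len=250, evalue=1e-30, s_len=400)
        assert annotate_function(self.orf(300), [hit]) is None

    def test_coverage_rule(self):
        # 150 of 300 aa aligned (50 %) -> rejected
        hit = make_hit(query_id="o1", aln_len=150, evalue=1e-30, s_len=310)
        assert annotate_function(self.orf(300), [hit]) is None

    def test_all_rules_pass(self):
        hit = make_hit(query_id="o1", aln_len=210, evalue=1e-6, s_len=330)
        ann = annotate_function(self.orf(300), [hit],
                                ec_numbers={"s": "4.2.1.17"})
        assert ann is not None
        assert ann.ec_number == "4.2.1.17"
        assert ann.pct_query_aligned == pytest.approx(0.7)
        assert ann.len_ratio == pytest.approx(330 / 300)

    def test_evalue_rule_and_tie_break(self):
        weak = make_hit(query_id="o1", subject_id="a", aln_len=210,
                        evalue=1e-4, s_len=300)
        assert annotate_function(self.orf(300), [weak]) is None
        h1 = make_hit(query_id="o1", subject_id="b", aln_len=210,
                      evalue=1e-8, s_len=300, bitscore=90)
        h2 = make_hit(query_id="o1", subject_id="a", aln_len=210,
                      evalue=1e-8, s_len=300, bitscore=90)
        ann = annotate_function(self.orf(300), [h1, h2])
        assert ann.reference_id == "a"   # id breaks the tie


class TestEqualEvalueScreen:
    def test_equal_evalue_out_of_class_flagged(self):
        hits = [make_hit(query_id="o1", subject_id="in", evalue=1e-80,
                         subject_class="Betaproteobacteria", aln_len=65,
                         q_len=100),
                make_hit(query_id="o1", subject_id="out", evalue=1e-80,
                         subject_class="Chlorobia", aln_len=65, q_len=100)]
        assert screen_equal_evalue_out_of_class(
            ["o1"], hits, "Betaproteobacteria") == ["o1"]

    def test_nearly_equal_not_flagged(self):
        hits = [make_hit(query_id="o1", subject_id="in", evalue=1e-80,
                         subject_class="Betaproteobacteria", aln_len=65,
                         q_len=100),
                make_hit(query_id="o1", subject_id="out", evalue=1e-79,
                         subject_class="Chlorobia", aln_len=65, q_len=100)]
        assert screen_equal_evalue_out_of_class(
            ["o1"], hits, "Betaproteobacteria") == []

    def test_low_coverage_not_flagged(self):
        hits = [make_hit(query_id="o1", subject_id="in", evalue=1e-80,
                         subject_class="Betaproteobacteria", aln_len=50,
                         q_len=100),
                make_hit(query_id="o1", subject_id="out", evalue=1e-80,
                         subject_class="Chlorobia", aln_len=50, q_len=100)]
        assert screen_equal_evalue_out_of_class(
            ["o1"], hits, "Betaproteobacteria") == []


class TestMgeFilter:
    def base_hit(self, **kw):
        defaults = dict(query_id="o1", subject_id="m1", evalue=1e-40,
                        aln_len=200, q_len=300, s_len=300,
                        subject_class="Chlorobia")
        defaults.update(kw)
        return make_hit(**defaults)

    def test_subject_side_coverage_rule(self):
        # 200/300 = 66.7 % of query but 200/500 = 40 % of subject
        hit = self.base_hit(s_len=500)
        assert mge_homology_filter(["o1"], [hit],
                                   {"o1": "Betaproteobacteria"}) == []

    def test_evalue_threshold(self):
        hit = self.base_hit(evalue=1e-29)
        assert mge_homology_filter(["o1"], [hit],
                                   {"o1": "Betaproteobacteria"}) == []

    def test_same_class_rejected(self):
        hit = self.base_hit(subject_class="Betaproteobacteria")
        assert mge_homology_filter(["o1"], [hit],
                                   {"o1": "Betaproteobacteria"}) == []

    def test_passing_hit(self):
        assert mge_homology_filter(["o1"], [self.base_hit()],
                                   {"o1": "Betaproteobacteria"}) == ["o1"]

    def test_hit_without_subject_length_skipped(self, caplog):
        hit = self.base_hit(s_len=None)
        import logging
        with caplog.at_level(logging.WARNING, logger="lgtscan"):
            out = mge_homology_filter(["o1"], [hit],
                                      {"o1": "Betaproteobacteria"})
        assert out == [] and "lacks subject length" in caplog.text

    def test_monotone_in_thresholds(self):
        """Tightening any threshold never adds survivors."""
        rng = np.random.default_rng(9)
        hits = [self.base_hit(query_id=f"o{i}",
                              evalue=10.0 ** -rng.uniform(20, 60),
                              aln_len=int(rng.uniform(100, 300)))
                for i in range(30)]
        classes = {f"o{i}": "Betaproteobacteria" for i in range(30)}
        ids = [f"o{i}" for i in range(30)]
        loose = set(mge_homology_filter(ids, hits, classes,
                                        PipelineConfig()))
        tighter = PipelineConfig(mge_evalue=1e-40, mge_coverage=0.8)
        tight = set(mge_homology_filter(ids, hits, classes, tighter))
        assert tight <= loose


class TestReadMapping:
    def test_coverage_boundary_70_percent(self):
        rng = np.random.default_rng(2)
        # C-free contig so the read's C tail can never extend an alignment
        contig = "".join("AGT"[i] for i in rng.integers(0, 3, 2000))
        cfg = PipelineConfig(read_evalue=10.0)  # isolate the coverage rule
        # read: 69 vs 70 matching nt out of 100 (tail cannot align)
        for matched, kept in [(69, False), (70, True)]:
            read = contig[500:500 + matched] + "C" * (100 - matched)
            mapped = map_reads_to_contigs([("r", read)], [("c", contig)],
                                          cfg)
            assert bool(mapped) == kept, matched

    def test_full_length_exact_read_retained(self):
        rng = np.random.default_rng(2)
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        read = contig[100:600]
        mapped = map_reads_to_contigs([("r", read)], [("c", contig)])
        assert mapped == [("r", "c", 101, 600)]

    def test_weak_evalue_rejected(self):
        # a short exact match passes coverage but not the e-value bar
        rng = np.random.default_rng(2)
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        read = contig[50:100]  # 50 nt: E ~ 1e-11 >> 1e-30
        assert map_reads_to_contigs([("r", read)], [("c", contig)]) == []

    def test_reverse_strand_read_maps(self):
        from lgtscan.composition import reverse_complement
        rng = np.random.default_rng(2)
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        read = reverse_complement(contig[100:600])
        mapped = map_reads_to_contigs([("r", read)], [("c", contig)])
        assert mapped == [("r", "c", 101, 600)]


class TestReadSpans:
    ORF = OrfRecord("orf", "c", 100, 400, "+")
    NEIGHBOR = OrfRecord("nb", "c", 450, 700, "+")

    def classify(self, start, end):
        evs = classify_read_spans([("r", "c", start, end)], self.ORF,
                                  [self.NEIGHBOR])
        return evs[0].span_class if evs else None

    def test_into_neighbor(self):
        assert self.classify(50, 450) == "into_neighbor"

    def test_full_orf(self):
        assert self.classify(90, 410) == "full_orf"

    def test_partial(self):
        assert self.classify(150, 350) == "partial"

    def test_intergenic_bounded(self):
        assert self.classify(50, 250) == "intergenic_bounded"

    def test_no_overlap_ignored(self):
        assert self.classify(1, 50) is None

    def test_classes_exclusive_exhaustive(self):
        """Every overlapping alignment gets exactly one class."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            s = int(rng.integers(1, 800))
            e = s + int(rng.integers(1, 400))
            evs = classify_read_spans([("r", "c", s, e)], self.ORF,
                                      [self.NEIGHBOR])
            overlaps = not (e < 100 or s > 400)
            assert len(evs) == (1 if overlaps else 0)
            if evs:
                assert evs[0].span_class in {
                    "full_orf", "into_neighbor", "partial",
                    "intergenic_bounded"}
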