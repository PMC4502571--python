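"""Pairwise local alignment and the threshold filters built on it.

The built-in aligner is affine-gap Smith-Waterman (a gap of length L costs
``gap_open + (L - 1) * gap_extend``). E-values follow the Karlin-Altschul
formula E = K * m * n * exp(-lambda * S) with fixed constants (K = 0.13,
lambda = 0.32 for the default nucleotide scoring); because both sides of
every comparison in this package use the same statistics, the constants
cancel in all threshold decisions that compare e-values to each other.

Alignment coverage of the query is alignment columns / query length,
gap columns included.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align

from .core_io import AlignmentHit, OrfRecord, PipelineConfig
from .composition import reverse_complement

logger = logging.getLogger("lgtscan")

KARLIN_K = 0.13
KARLIN_LAMBDA = 0.32


@dataclass(frozen=True)
class ScoringParams:
    """Affine-gap scoring for the built-in local aligner."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0    # cost of the first column of a gap
    gap_extend: float = -2.0  # cost of each further column


@dataclass(frozen=True)
class FunctionalAnnotation:
    orf_id: str
    reference_id: str
    ec_number: Optional[str]
    pct_query_aligned: float   # fraction in (0, 1]
    evalue: float
    len_ratio: float           # max(len_q, len_s) / min(len_q, len_s)


@dataclass(frozen=True)
class ReadSpanEvidence:
    read_id: str
    contig_id: str
    orf_id: str
    span_class: str  # full_orf | into_neighbor | partial | intergenic_bounded


# ---------------------------------------------------------------------------
# Built-in local aligner
# ---------------------------------------------------------------------------

def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _alignment_stats(aln) -> tuple[int, int, int, int, int, int]:
    """(identities, columns, q_start, q_end, s_start, s_end) of a biopython
    alignment; coordinates 1-based inclusive on the aligned region."""
    identities = 0
    columns = 0
    q_blocks = aln.aligned[1]  # query = sequences[1]
    s_blocks = aln.aligned[0]  # subject = sequences[0]
    query = aln.sequences[1]
    subject = aln.sequences[0]
    prev_q_end = prev_s_end = None
    for (ss, se), (qs, qe) in zip(s_blocks, q_blocks):
        if prev_q_end is not None:
            columns += (qs - prev_q_end) + (ss - prev_s_end)  # gap columns
        for i in range(qe - qs):
            columns += 1
            if query[qs + i] == subject[ss + i]:
                identities += 1
        prev_q_end, prev_s_end = qe, se
    q_start = int(q_blocks[0][0]) + 1
    q_end = int(q_blocks[-1][1])
    s_start = int(s_blocks[0][0]) + 1
    s_end = int(s_blocks[-1][1])
    return identities, columns, q_start, q_end, s_start, s_end


def karlin_altschul_evalue(score: float, m: int, n: int,
                           K: float = KARLIN_K,
                           lam: float = KARLIN_LAMBDA) -> float:
    return K * m * n * math.exp(-lam * score)


def local_align(query: str, subject: str,
                query_id: str = "query", subject_id: str = "subject",
                scoring: ScoringParams = ScoringParams(),
                nucleotide: bool = True) -> Optional[AlignmentHit]:
    """Optimal affine-gap local alignment of query against subject.

    Nucleotide queries are aligned in both orientations and the better
    alignment kept (coordinates reported on the forward query). Returns
    None when no positive-scoring local alignment exists.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    aligner = _make_aligner(scoring)
    best = None
    best_rc = False
    for rc in ([False, True] if nucleotide else [False]):
        q = reverse_complement(query) if rc else query
        score = aligner.score(subject, q)
        if score > 0 and (best is None or score > best[0]):
            best = (score, q)
            best_rc = rc
    if best is None:
        return None
    score, q = best
    aln = aligner.align(subject, q)[0]
    ident, columns, q_start, q_end, s_start, s_end = _alignment_stats(aln)
    if best_rc:  # report on the forward strand of the query
        q_start, q_end = len(query) - q_end + 1, len(query) - q_start + 1
    m, n = len(query), len(subject)
    evalue = karlin_altschul_evalue(score, m, n)
    bitscore = (KARLIN_LAMBDA * score - math.log(KARLIN_K)) / math.log(2.0)
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id,
        pct_identity=100.0 * ident / columns, aln_len=columns,
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        evalue=evalue, bitscore=bitscore,
        q_len=len(query), s_len=len(subject))


def all_vs_all_hits(sequences: Mapping[str, str],
                    scoring: ScoringParams = ScoringParams(),
                    nucleotide: bool = False,
                    seed_kmer: int = 6,
                    max_evalue: float = 10.0) -> list[AlignmentHit]:
    """All-vs-all local alignment with an exact-k-mer candidate filter.

    Pairs sharing no exact ``seed_kmer``-mer are never aligned (a
    seed-style candidate filter; unrelated sequences essentially never
    share one). Emits one hit per ordered pair direction that aligns.
    """
    ids = sorted(sequences)
    kindex: dict[str, set[int]] = {}
    for i, sid in enumerate(ids):
        s = sequences[sid]
        for j in range(len(s) - seed_kmer + 1):
            kindex.setdefault(s[j:j + seed_kmer], set()).add(i)
    candidates: set[tuple[int, int]] = set()
    for members in kindex.values():
        if len(members) < 2:
            continue
        mem = sorted(members)
        for a in range(len(mem)):
            for b in range(a + 1, len(mem)):
                candidates.add((mem[a], mem[b]))
    hits: list[AlignmentHit] = []
    for a, b in sorted(candidates):
        qa, qb = ids[a], ids[b]
        hit = local_align(sequences[qa], sequences[qb], qa, qb,
                          scoring, nucleotide=nucleotide)
        if hit is None or hit.evalue > max_evalue:
            continue
        hits.append(hit)
        # symmetric direction: same alignment, roles swapped
        hits.append(AlignmentHit(
            query_id=qb, subject_id=qa, pct_identity=hit.pct_identity,
            aln_len=hit.aln_len, q_start=hit.s_start, q_end=hit.s_end,
            s_start=hit.q_start, s_end=hit.q_end, evalue=hit.evalue,
            bitscore=hit.bitscore, q_len=hit.s_len, s_len=hit.q_len))
    return hits


# ---------------------------------------------------------------------------
# Annotation and screens
# ---------------------------------------------------------------------------

def _query_len(hit: AlignmentHit,
               lengths: Optional[Mapping[str, int]] = None) -> Optional[int]:
    if hit.q_len is not None:
        return hit.q_len
    if lengths is not None:
        return lengths.get(hit.query_id)
    return None


def _subject_len(hit: AlignmentHit,
                 lengths: Optional[Mapping[str, int]] = None) -> Optional[int]:
    if hit.s_len is not None:
        return hit.s_len
    if lengths is not None:
        return lengths.get(hit.subject_id)
    return None


def annotate_function(orf: OrfRecord, hits: Sequence[AlignmentHit],
                      config: Optional[PipelineConfig] = None,
                      subject_lengths: Optional[Mapping[str, int]] = None,
                      ec_numbers: Optional[Mapping[str, str]] = None,
                      ) -> Optional[FunctionalAnnotation]:
    """Annotate an ORF from its protein-level hits: the best-e-value hit
    that (a) aligns over at least ``annot_coverage`` of the predicted
    protein, (b) has e-value <= ``annot_evalue``, and (c) has neither
    sequence longer than ``annot_len_ratio`` times the other.

    Ties on e-value break by bitscore, then subject id. ``ec_numbers``
    maps reference ids to EC numbers.
    """
    config = config or PipelineConfig()
    qlen = len(orf.protein)
    passing = []
    for h in hits:
        if h.query_id != orf.id:
            continue
        slen = _subject_len(h, subject_lengths)
        if slen is None:
            logger.warning("annotate_function: hit %s->%s lacks subject "
                           "length; skipped", h.query_id, h.subject_id)
            continue
        if h.evalue > config.annot_evalue:
            continue
        if qlen == 0 or h.aln_len / qlen < config.annot_coverage:
            continue
        if max(qlen, slen) > config.annot_len_ratio * min(qlen, slen):
            continue
        passing.append((h, slen))
    if not passing:
        return None
    best, slen = min(passing,
                     key=lambda t: (t[0].evalue, -t[0].bitscore,
                                    t[0].subject_id))
    ec = None
    if ec_numbers is not None:
        ec = ec_numbers.get(best.subject_id)
    return FunctionalAnnotation(
        orf_id=orf.id, reference_id=best.subject_id, ec_number=ec,
        pct_query_aligned=best.aln_len / qlen, evalue=best.evalue,
        len_ratio=max(qlen, slen) / min(qlen, slen))


def screen_equal_evalue_out_of_class(
        genome_orf_ids: Iterable[str], hits: Sequence[AlignmentHit],
        home_class: str,
        query_lengths: Optional[Mapping[str, int]] = None,
        min_coverage: float = 0.60) -> list[str]:
    """Self-genome screen: flag ORFs with an out-of-class hit whose
    e-value EQUALS the best overall hit's e-value and whose alignment
    covers at least ``min_coverage`` of the query."""
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    flagged = []
    for oid in genome_orf_ids:
        qhits = by_query.get(oid, [])
        if not qhits:
            continue
        best_e = min(h.evalue for h in qhits)
        for h in qhits:
            if h.subject_class is None or h.subject_class == home_class:
                continue
            if h.evalue != best_e:
                continue
            qlen = _query_len(h, query_lengths)
            if qlen is None or h.aln_len / qlen < min_coverage:
                continue
            flagged.append(oid)
            break
    return flagged


def mge_homology_filter(candidate_orf_ids: Iterable[str],
                        mge_hits: Sequence[AlignmentHit],
                        orf_classes: Mapping[str, str],
                        config: Optional[PipelineConfig] = None,
                        query_lengths: Optional[Mapping[str, int]] = None,
                        subject_lengths: Optional[Mapping[str, int]] = None,
                        ) -> list[str]:
    """Keep candidates with at least one hit to a mobile-element sequence
    of a different taxonomic class, with e-value <= ``mge_evalue`` and an
    alignment covering >= ``mge_coverage`` of BOTH query and subject."""
    config = config or PipelineConfig()
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in mge_hits:
        by_query.setdefault(h.query_id, []).append(h)
    kept = []
    for oid in candidate_orf_ids:
        orf_class = orf_classes.get(oid)
        for h in by_query.get(oid, []):
            if h.evalue > config.mge_evalue:
                continue
            if h.subject_class is None or h.subject_class == orf_class:
                continue
            qlen = _query_len(h, query_lengths)
            slen = _subject_len(h, subject_lengths)
            if slen is None:
                logger.warning("mge filter: hit %s->%s lacks subject length; "
                               "skipped", h.query_id, h.subject_id)
                continue
            if qlen is None:
                logger.warning("mge filter: hit %s->%s lacks query length; "
                               "skipped", h.query_id, h.subject_id)
                continue
            if (h.aln_len / qlen >= config.mge_coverage
                    and h.aln_len / slen >= config.mge_coverage):
                kept.append(oid)
                break
    return kept


# ---------------------------------------------------------------------------
# Read-mapping validation
# ---------------------------------------------------------------------------

def map_reads_to_contigs(reads: Sequence[tuple[str, str]],
                         contigs: Sequence[tuple[str, str]],
                         config: Optional[PipelineConfig] = None,
                         scoring: ScoringParams = ScoringParams(),
                         seed_kmer: Optional[int] = None,
                         ) -> list[tuple[str, str, int, int]]:
    """Align reads to contigs; keep alignments covering at least
    ``read_coverage`` of the read with e-value <= ``read_evalue``.

    Returns (read_id, contig_id, contig_start, contig_end) with 1-based
    inclusive contig coordinates; a read may map to several contigs.
    A read found verbatim in a contig (either strand) short-circuits the
    dynamic programming (the full-length exact match is the optimal local
    alignment). With ``seed_kmer`` set, read/contig pairs sharing no
    exact k-mer are skipped entirely.
    """
    config = config or PipelineConfig()
    indexes = None
    if seed_kmer is not None:
        indexes = []
        for _, cseq in contigs:
            idx = {cseq[i:i + seed_kmer]
                   for i in range(len(cseq) - seed_kmer + 1)}
            indexes.append(idx)
    mapped = []
    for rid, rseq in reads:
        rc = reverse_complement(rseq)
        for ci, (cid, cseq) in enumerate(contigs):
            if indexes is not None:
                shared = any(
                    rseq[i:i + seed_kmer] in indexes[ci]
                    or rc[i:i + seed_kmer] in indexes[ci]
                    for i in range(0, len(rseq) - seed_kmer + 1, seed_kmer))
                if not shared:
                    continue
            pos = cseq.find(rseq)
            if pos < 0:
                pos = cseq.find(rc)
            if pos >= 0:  # exact full-length match
                score = scoring.match * len(rseq)
                evalue = karlin_altschul_evalue(score, len(rseq), len(cseq))
                if evalue <= config.read_evalue:
                    mapped.append((rid, cid, pos + 1, pos + len(rseq)))
                continue
            hit = local_align(rseq, cseq, rid, cid, scoring, nucleotide=True)
            if hit is None:
                continue
            if hit.aln_len / len(rseq) < config.read_coverage:
                continue
            if hit.evalue > config.read_evalue:
                continue
            mapped.append((rid, cid, hit.s_start, hit.s_end))
    return mapped


def classify_read_spans(mapped_reads: Sequence[tuple[str, str, int, int]],
                        orf: OrfRecord,
                        neighbor_orfs: Sequence[OrfRecord],
                        ) -> list[ReadSpanEvidence]:
    """Classify read alignments that overlap an ORF (1-based inclusive
    coordinates throughout).

    into_neighbor: overlaps the ORF and >= 1 nt of an adjacent ORF;
    full_orf: covers the whole ORF without touching a neighbor;
    intergenic_bounded: at least one alignment end lies outside the ORF in
    intergenic sequence (and no neighbor is touched, ORF not fully
    covered); partial: contained within the ORF.
    """
    out = []
    for rid, cid, a_start, a_end in mapped_reads:
        if cid != orf.contig_id:
            continue
        if a_end < orf.start or a_start > orf.end:
            continue  # no overlap with the ORF
        touches_neighbor = any(
            n.contig_id == cid and a_end >= n.start and a_start <= n.end
            for n in neighbor_orfs)
        if touches_neighbor:
            cls = "into_neighbor"
        elif a_start <= orf.start and a_end >= orf.end:
            cls = "full_orf"
        elif a_start < orf.start or a_end > orf.end:
            cls = "intergenic_bounded"
        else:
            cls = "partial"
        out.append(ReadSpanEvidence(read_id=rid, contig_id=cid,
                                    orf_id=orf.id, span_class=cls))
    return out
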