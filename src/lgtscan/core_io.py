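"""Domain types and on-disk formats shared across the pipeline.

Coordinate convention: ORF coordinates are 1-based and inclusive on both
ends (GFF3 style). All arithmetic that touches coordinates documents this
at the boundary.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("lgtscan")

NUCLEOTIDES = "ACGT"
CONTIG_ALPHABET = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig from a community metagenome."""

    id: str
    sequence: str
    community: str = ""

    def __post_init__(self):
        bad = set(self.sequence) - CONTIG_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id}: non-ACGTN characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """A predicted protein-coding ORF on a contig.

    start/end are 1-based inclusive nucleotide positions on the contig;
    strand '+' means the coding sequence reads left to right.
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str = ""
    annotation: Optional[str] = None  # EC number if any
    product: Optional[str] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"ORF {self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"ORF {self.id}: strand must be '+' or '-'")

    @property
    def nt_length(self) -> int:
        # inclusive 1-based span
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local-alignment result (12-column tabular dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_class: Optional[str] = None
    q_len: Optional[int] = None
    s_len: Optional[int] = None

    def __post_init__(self):
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.aln_len < 1:
            raise ValueError(f"aln_len must be >= 1, got {self.aln_len}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")


@dataclass
class PipelineConfig:
    """Every numeric threshold used by the pipeline, with printed defaults."""

    min_contig_len: int = 1000          # nt
    nb_improvement: float = 0.15        # relative per-base log-likelihood gain
    group2_order_gap: float = 10.0      # orders of magnitude between e-values
    group3_ratio: float = 1.5           # NB likelihood ratio
    net_identity: float = 70.0          # % identity for homology-network edges
    net_coverage: float = 0.60          # query coverage for network edges
    net_evalue: float = 1e-5
    subtree_support: float = 70.0       # % support for subtree extraction
    subtree_max_leaves: int = 200
    patristic_cutoff: float = 0.3       # substitutions/site
    mge_evalue: float = 1e-30
    mge_coverage: float = 0.60          # of query AND of subject
    annot_evalue: float = 1e-5
    annot_coverage: float = 0.60        # of the predicted protein
    annot_len_ratio: float = 1.2
    read_coverage: float = 0.70         # of the read
    read_evalue: float = 1e-30
    kmer_order: int = 4                 # k-mer length of the composition model
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("nb_improvement", "net_coverage", "mge_coverage",
                     "annot_coverage", "read_coverage"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_contig_len < 1:
            raise ValueError("min_contig_len must be >= 1")
        if self.kmer_order < 1:
            raise ValueError("kmer_order must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a JSON object; unknown keys are an error."""
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# type alias used throughout: sequence/genome id -> class label
TaxonomyMap = Mapping[str, str]

# a phylogenetic tree is a dendropy Tree; leaves are taxa whose labels are
# sequence ids, internal node .label (when parseable as float) is % support
PhyloTree = dendropy.Tree


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA, returning (id, sequence) in file order.

    Ids are the first whitespace-delimited token of each header. A sequence
    line before the first header is a parse error naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: expected FASTA header, got {line.strip()!r}")
            break
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read sequences from FASTA or FASTQ (qualities discarded)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(path), "fastq")]
    return read_fasta(path)


def read_contigs(path: str | Path, community: str = "") -> list[ContigRecord]:
    return [ContigRecord(i, s, community) for i, s in read_fasta(path)]


# ---------------------------------------------------------------------------
# ORF tables
# ---------------------------------------------------------------------------

_ORF_COLUMNS = ["orf_id", "contig_id", "start", "end", "strand", "ec_number",
                "product"]


def read_orf_table(path: str | Path,
                   proteins: Optional[Mapping[str, str]] = None,
                   ) -> list[OrfRecord]:
    """Read the 7-column ORF call table (header line required).

    Columns: orf_id, contig_id, start, end, strand, ec_number, product;
    '.' marks a missing EC number or product. `proteins` maps orf_id to its
    amino-acid sequence (from the companion protein FASTA).
    """
    proteins = proteins or {}
    orfs = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _ORF_COLUMNS:
            raise ValueError(f"{path}: bad ORF table header {header}")
        for rowno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_ORF_COLUMNS):
                raise ValueError(f"{path}:{rowno}: expected "
                                 f"{len(_ORF_COLUMNS)} columns, got {len(row)}")
            oid, cid, start, end, strand, ec, product = row
            orfs.append(OrfRecord(
                id=oid, contig_id=cid, start=int(start), end=int(end),
                strand=strand, protein=proteins.get(oid, ""),
                annotation=None if ec == "." else ec,
                product=None if product == "." else product))
    return orfs


def write_orf_table(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ORF_COLUMNS)
        for o in orfs:
            w.writerow([o.id, o.contig_id, o.start, o.end, o.strand,
                        o.annotation or ".", o.product or "."])


def validate_orfs(orfs: Sequence[OrfRecord],
                  contigs: Sequence[ContigRecord]) -> None:
    """Check every ORF lies within its parent contig."""
    lengths = {c.id: c.length for c in contigs}
    for o in orfs:
        if o.contig_id not in lengths:
            raise ValueError(f"ORF {o.id}: unknown contig {o.contig_id}")
        if o.end > lengths[o.contig_id] or o.start < 1:
            raise ValueError(
                f"ORF {o.id}: span [{o.start},{o.end}] outside contig "
                f"{o.contig_id} (length {lengths[o.contig_id]})")


# ---------------------------------------------------------------------------
# Taxonomy and pathway tables
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a 2-column id<TAB>class table."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_taxonomy(taxonomy: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(taxonomy):
            fh.write(f"{sid}\t{taxonomy[sid]}\n")


def read_pathway_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read an EC<TAB>pathway table (one membership per row) into a map
    EC number -> set of pathway labels."""
    tmp: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            tmp.setdefault(parts[0], set()).add(parts[1])
    return {ec: frozenset(v) for ec, v in tmp.items()}


# ---------------------------------------------------------------------------
# 12-column tabular hit files
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path,
                   taxonomy: Optional[TaxonomyMap] = None,
                   ) -> list[AlignmentHit]:
    """Read 12-column tabular search output (qid, sid, pident, length,
    mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore).

    Extra trailing columns 13 and 14, when present, are read as query and
    subject lengths; any further columns are ignored. subject_class is
    filled from `taxonomy` when the subject id is mapped.
    """
    taxonomy = taxonomy or {}
    hits = []
    with open(path) as fh:
        for rowno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}:{rowno}: expected >= 12 tab-separated columns, "
                    f"got {len(parts)}")
            (qid, sid, pident, length, _mm, _go,
             qstart, qend, sstart, send, evalue, bitscore) = parts[:12]
            q_len = int(parts[12]) if len(parts) > 12 and parts[12] else None
            s_len = int(parts[13]) if len(parts) > 13 and parts[13] else None
            hits.append(AlignmentHit(
                query_id=qid, subject_id=sid, pct_identity=float(pident),
                aln_len=int(length), q_start=int(qstart), q_end=int(qend),
                s_start=int(sstart), s_end=int(send), evalue=float(evalue),
                bitscore=float(bitscore),
                subject_class=taxonomy.get(sid), q_len=q_len, s_len=s_len))
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path,
                    with_lengths: bool = True) -> None:
    with open(path, "w") as fh:
        for h in hits:
            row = [h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                   str(h.aln_len), "0", "0", str(h.q_start), str(h.q_end),
                   str(h.s_start), str(h.s_end), f"{h.evalue:.3g}",
                   f"{h.bitscore:.1f}"]
            if with_lengths:
                row += [str(h.q_len or ""), str(h.s_len or "")]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> PhyloTree:
    """Read a Newick tree; internal node labels are kept as support values.

    Branches with no stated length are set to 0.0 with a logged warning.
    A Newick string (containing ';') may be passed directly.
    """
    text = str(source)
    if ";" not in text:
        text = Path(source).read_text()
    tree = dendropy.Tree.get(
        data=text, schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
        rooting="force-rooted")
    missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing += 1
        elif edge.length < 0:
            raise ValueError("negative branch length in tree")
    if missing:
        logger.warning("read_newick: %d branch lengths missing, set to 0.0",
                       missing)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: PhyloTree, path: Optional[str | Path] = None) -> str:
    """Write Newick preserving branch lengths (>= 6 significant digits)
    and internal support labels; returns the string."""
    text = tree.as_string(
        schema="newick", suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g").strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def node_support(node: dendropy.Node) -> Optional[float]:
    """Support value of an internal node (percent), if annotated."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Length filter
# ---------------------------------------------------------------------------

def filter_contigs_by_length(contigs: Sequence[ContigRecord],
                             min_len: int) -> list[ContigRecord]:
    """Keep contigs whose length is at least ``min_len`` (order preserved)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [c for c in contigs if c.length >= min_len]
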