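"""Synthetic metagenome communities with planted inter-class transfers.

Everything the pipeline consumes can be generated here with machine-
readable ground truth: class-specific nucleotide composition models,
contigs carrying ORFs, planted ORF insertions regenerated from a donor
class's composition, error-free reads, a mobile-element protein database
containing homologs of planted ORFs, reference homology-hit tables, and
simulated protein families in which a community leaf is grafted into a
donor clade at a stated patristic distance.

Class composition models are built around realistic marginal base
frequencies: classes are spread over a GC-content range of 30-70 % with a
small alternating purine skew, scaled by a ``divergence`` knob (0 means
all classes share uniform base frequencies). Per-context conditional
distributions share a common context jitter so the class signal is purely
compositional.

Protein families evolve under a 20-state Jukes-Cantor-like process: along
a branch of length b substitutions/site, each site changes with
probability (19/20)(1 - exp(-20 b / 19)) to a uniformly chosen different
amino acid, so Poisson-corrected distances on the simulated alignments
estimate the generating branch lengths with only mild downward bias at
the depths used here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .composition import KmerClassModel, reverse_complement
from .core_io import (ContigRecord, OrfRecord, AlignmentHit, write_fasta,
                      write_hit_table, write_orf_table, write_taxonomy)

logger = logging.getLogger("lgtscan")

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}

DEFAULT_CLASS_LABELS = (
    "Betaproteobacteria", "Gammaproteobacteria", "Alphaproteobacteria",
    "Actinobacteria", "Bacilli", "Chlorobia", "Cytophagia", "Deltaproteobacteria",
)

# codon -> amino acid (standard code), and its inverse
_CODONS = {}
for b1 in _BASES:
    for b2 in _BASES:
        for b3 in _BASES:
            codon = b1 + b2 + b3
            if codon in _STOPS:
                continue
            _CODONS[codon] = str(Seq(codon).translate())
_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in _CODONS.items():
    _SYNONYMS.setdefault(aa, []).append(codon)


# ---------------------------------------------------------------------------
# Class composition models
# ---------------------------------------------------------------------------

def _class_base_frequencies(n_classes: int, divergence: float) -> np.ndarray:
    """Marginal base frequencies per class: GC content spread over
    [0.30, 0.70] with alternating purine skew, scaled by divergence."""
    gcs = np.linspace(0.30, 0.70, n_classes)
    patterns = np.empty((n_classes, 4))
    for i, gc in enumerate(gcs):
        skew = 0.04 * (1 if i % 2 == 0 else -1)
        at = 1.0 - gc
        patterns[i] = [at / 2 + skew, gc / 2 - skew,
                       gc / 2 + skew, at / 2 - skew]  # A, C, G, T
    return 0.25 + divergence * (patterns - 0.25)


def sample_class_models(n_classes: int, k: int = 4, divergence: float = 1.0,
                        seed: int = 0,
                        class_labels: Optional[Sequence[str]] = None,
                        context_concentration: float = 8.0,
                        ) -> list[KmerClassModel]:
    """Deterministically construct ``n_classes`` composition models.

    The per-context conditional distribution of class i is the class's
    marginal base frequency vector modulated by a context-specific jitter
    shared across classes (so divergence = 0 yields identical models).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must be in [0, 1]")
    labels = list(class_labels or DEFAULT_CLASS_LABELS)
    if n_classes > len(labels):
        labels += [f"Class{i}" for i in range(len(labels), n_classes)]
    rng = np.random.default_rng(seed)
    n_ctx = 4 ** (k - 1)
    jitter_shared = rng.dirichlet([context_concentration] * 4, size=n_ctx)
    freqs = _class_base_frequencies(n_classes, divergence)
    models = []
    for i in range(n_classes):
        # lineage-specific oligonucleotide usage on top of the GC signal,
        # blended with the shared context structure by the divergence knob
        jitter_own = rng.dirichlet([context_concentration] * 4, size=n_ctx)
        jitter = (jitter_shared ** (1.0 - divergence)
                  * jitter_own ** divergence)
        probs = freqs[i] * jitter
        probs /= probs.sum(axis=1, keepdims=True)
        models.append(KmerClassModel(
            class_label=labels[i], k=k, log_probs=np.log(probs),
            pseudocount=0.0))
    return models


def model_marginal(model: KmerClassModel) -> np.ndarray:
    """Mean conditional base distribution over contexts."""
    probs = np.exp(model.log_probs)
    return probs.mean(axis=0)


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2) between two distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = (p + q) / 2.0

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def pairwise_js_divergence(models: Sequence[KmerClassModel]) -> np.ndarray:
    """Realized pairwise JS divergence between class marginal base
    distributions (bits)."""
    n = len(models)
    marg = [model_marginal(m) for m in models]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = js_divergence(marg[i], marg[j])
    return out


# ---------------------------------------------------------------------------
# Sequence sampling
# ---------------------------------------------------------------------------

def sample_sequence(model: KmerClassModel, length: int,
                    rng: np.random.Generator) -> str:
    """Sample a nucleotide sequence from the class Markov chain."""
    probs = np.exp(model.log_probs)
    cum = probs.cumsum(axis=1)
    marginal = model_marginal(model)
    marg_cum = marginal.cumsum()
    k = model.k
    n_ctx = model.n_contexts
    out = []
    ctx = 0
    u = rng.random(length)
    for i in range(length):
        if i < k - 1:
            b = int(np.searchsorted(marg_cum, u[i] * marg_cum[-1]))
        else:
            row = cum[ctx]
            b = int(np.searchsorted(row, u[i] * row[-1]))
        b = min(b, 3)
        out.append(_BASES[b])
        ctx = (ctx * 4 + b) % n_ctx if k > 1 else 0
    return "".join(out)


class _ChainCodonSampler:
    """Codon sampling that follows a class Markov chain (keeps the k-mer
    context signal inside coding sequence)."""

    def __init__(self, model: KmerClassModel, rng: np.random.Generator):
        self.probs = np.exp(model.log_probs)
        self.k = model.k
        self.n_ctx = model.n_contexts
        self.rng = rng
        self.ctx = 0
        self._codon_cache: dict[int, np.ndarray] = {}

    def prime(self, seq: str) -> None:
        """Advance the running context over already-emitted sequence."""
        for b in seq[-(self.k - 1):] if self.k > 1 else "":
            self.ctx = (self.ctx * 4 + _BASES.index(b)) % self.n_ctx

    def _codon_probs(self) -> np.ndarray:
        """Chain probability of each of the 64 codons from the current
        context (cached per context)."""
        cached = self._codon_cache.get(self.ctx)
        if cached is not None:
            return cached
        out = np.empty(64)
        for ci in range(64):
            b1, b2, b3 = ci // 16, (ci // 4) % 4, ci % 4
            c1 = self.ctx
            p = self.probs[c1, b1]
            c2 = (c1 * 4 + b1) % self.n_ctx
            p *= self.probs[c2, b2]
            c3 = (c2 * 4 + b2) % self.n_ctx
            p *= self.probs[c3, b3]
            out[ci] = p
        self._codon_cache[self.ctx] = out
        return out

    def _advance(self, codon: str) -> None:
        for b in codon:
            self.ctx = (self.ctx * 4 + _BASES.index(b)) % self.n_ctx

    def sample_codon(self, aa: Optional[str] = None,
                     stop: bool = False) -> str:
        """Sample one codon from the chain; restricted to synonyms of
        ``aa`` when given, to stop codons when ``stop``, otherwise to any
        sense codon."""
        cp = self._codon_probs()
        if stop:
            allowed = list(_STOPS)
        elif aa is not None:
            allowed = _SYNONYMS[aa]
        else:
            allowed = list(_CODONS)
        idx = [(_BASES.index(c[0]) * 16 + _BASES.index(c[1]) * 4
                + _BASES.index(c[2])) for c in allowed]
        w = cp[idx]
        total = w.sum()
        w = w / total if total > 0 else np.full(len(allowed),
                                                1.0 / len(allowed))
        codon = allowed[int(self.rng.choice(len(allowed), p=w))]
        self._advance(codon)
        return codon


def sample_orf_nt(model: KmerClassModel, aa_len: int,
                  rng: np.random.Generator) -> str:
    """Sample an open reading frame (ATG + aa_len sense codons + stop)
    from the class Markov chain, rejecting in-frame stops."""
    sampler = _ChainCodonSampler(model, rng)
    sampler.prime("ATG")
    codons = ["ATG"]
    for _ in range(aa_len):
        codons.append(sampler.sample_codon())
    codons.append(sampler.sample_codon(stop=True))
    return "".join(codons)


def reverse_translate(protein: str, model: KmerClassModel,
                      rng: np.random.Generator) -> str:
    """Encode a protein as codons sampled from the class Markov chain
    restricted to each residue's synonymous codons (codon-usage bias
    consistent with the class's k-mer composition)."""
    sampler = _ChainCodonSampler(model, rng)
    sampler.prime("ATG")
    return "".join(sampler.sample_codon(aa=a) for a in protein)


# ---------------------------------------------------------------------------
# Contigs and planted events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth for one synthetic transfer."""

    event_id: str
    donor_class: str
    recipient_class: str
    contig_id: str
    orf_id: str
    start: int
    end: int
    strand: str
    ec_number: Optional[str] = None
    mge_homolog_id: Optional[str] = None
    mobility_neighbor: bool = False


def generate_contig(model: KmerClassModel, length: int,
                    orf_layout: Sequence[tuple[int, int, str]],
                    seed: int, contig_id: str = "c1",
                    community: str = "AU",
                    ) -> tuple[ContigRecord, list[OrfRecord]]:
    """Sample a contig from a class model and overwrite in-frame ORFs
    (ATG ... stop) onto the background at the given 1-based inclusive
    spans. Span lengths must be multiples of 3 with room for start and
    stop codons; spans must not overlap."""
    rng = np.random.default_rng(seed)
    spans = sorted(orf_layout)
    prev_end = 0
    for start, end, strand in spans:
        if start <= prev_end:
            raise ValueError(f"overlapping ORF spans at {start}")
        if start < 1 or end > length:
            raise ValueError(f"ORF span [{start},{end}] outside contig")
        if (end - start + 1) % 3 != 0 or end - start + 1 < 9:
            raise ValueError("ORF span must be a multiple of 3 and >= 9 nt")
        prev_end = end
    seq = list(sample_sequence(model, length, rng))
    orfs = []
    for i, (start, end, strand) in enumerate(spans, start=1):
        aa_len = (end - start + 1) // 3 - 2
        cds = sample_orf_nt(model, aa_len, rng)
        placed = cds if strand == "+" else reverse_complement(cds)
        seq[start - 1:end] = placed  # 1-based inclusive -> python slice
        protein = str(Seq(cds).translate())[:-1]  # strip the stop
        orfs.append(OrfRecord(id=f"{contig_id}_orf{i}", contig_id=contig_id,
                              start=start, end=end, strand=strand,
                              protein=protein))
    return ContigRecord(contig_id, "".join(seq), community), orfs


def plant_lgt(contig: ContigRecord, orfs: Sequence[OrfRecord], orf_id: str,
              donor_model: KmerClassModel, seed: int,
              recipient_class: str,
              ec_number: Optional[str] = None,
              mge_homolog: bool = False,
              mobility_neighbor: bool = False,
              protein: Optional[str] = None,
              event_id: str = "ev1",
              ) -> tuple[ContigRecord, list[OrfRecord], PlantedEvent,
                         Optional[tuple[str, str, str]]]:
    """Replace one ORF's sequence with donor-composition sequence.

    When ``protein`` is given the ORF encodes exactly that protein via
    donor-weighted reverse translation (the protein must start with M and
    fit the span); otherwise a fresh ORF is sampled from the donor model.
    Returns the modified contig and ORF list, the truth record, and an
    optional MGE database record (id, protein sequence, class) labelled
    with the recipient class.
    """
    rng = np.random.default_rng(seed)
    target = next((o for o in orfs if o.id == orf_id), None)
    if target is None:
        raise ValueError(f"no ORF {orf_id} on contig {contig.id}")
    span_aa = target.nt_length // 3 - 2
    if protein is not None:
        if not protein.startswith("M"):
            raise ValueError("planted protein must start with M")
        if len(protein) != span_aa + 1:
            raise ValueError(f"protein length {len(protein)} does not fit "
                             f"span ({span_aa + 1} aa incl. start)")
        cds = ("ATG" + reverse_translate(protein[1:], donor_model, rng)
               + _STOPS[int(rng.integers(0, 3))])
    else:
        cds = sample_orf_nt(donor_model, span_aa, rng)
    placed = cds if target.strand == "+" else reverse_complement(cds)
    seq = list(contig.sequence)
    seq[target.start - 1:target.end] = placed
    new_protein = str(Seq(cds).translate())[:-1]
    new_orfs = []
    neighbor_done = False
    ordered = sorted(orfs, key=lambda o: o.start)
    t_idx = next(i for i, o in enumerate(ordered) if o.id == orf_id)
    for i, o in enumerate(ordered):
        if o.id == orf_id:
            new_orfs.append(replace(o, protein=new_protein,
                                    annotation=ec_number))
        elif (mobility_neighbor and not neighbor_done
              and abs(i - t_idx) == 1):
            new_orfs.append(replace(o, product="IS4 family transposase"))
            neighbor_done = True
        else:
            new_orfs.append(o)
    if mobility_neighbor and not neighbor_done:
        raise ValueError(f"ORF {orf_id} has no neighbor for a mobility gene")
    mge_record = None
    mge_id = None
    if mge_homolog:
        mge_id = f"mge_{event_id}"
        mge_record = (mge_id, new_protein, recipient_class)
    event = PlantedEvent(
        event_id=event_id, donor_class=donor_model.class_label,
        recipient_class=recipient_class, contig_id=contig.id,
        orf_id=orf_id, start=target.start, end=target.end,
        strand=target.strand, ec_number=ec_number,
        mge_homolog_id=mge_id, mobility_neighbor=mobility_neighbor)
    return (ContigRecord(contig.id, "".join(seq), contig.community),
            new_orfs, event, mge_record)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def generate_reads(contigs: Sequence[ContigRecord], read_length: int,
                   coverage_depth: float, seed: int,
                   error_rate: float = 0.0) -> list[tuple[str, str]]:
    """Sample error-free (by default) reads with uniform start positions
    from both strands of each contig."""
    rng = np.random.default_rng(seed)
    reads = []
    for contig in contigs:
        if read_length > contig.length:
            raise ValueError(f"read length {read_length} exceeds contig "
                             f"{contig.id} length {contig.length}")
        n_reads = int(round(coverage_depth * contig.length / read_length))
        starts = rng.integers(0, contig.length - read_length + 1,
                              size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for i, (s, rc) in enumerate(zip(starts, strands), start=1):
            seq = contig.sequence[s:s + read_length]
            if rc:
                seq = reverse_complement(seq)
            if error_rate > 0:
                arr = list(seq)
                for pos in np.nonzero(rng.random(read_length) < error_rate)[0]:
                    arr[pos] = _BASES[int(rng.integers(0, 4))]
                seq = "".join(arr)
            reads.append((f"{contig.id}_read{i}", seq))
    return reads


# ---------------------------------------------------------------------------
# Protein families with grafted leaves
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("name", "length", "children")

    def __init__(self, name=None, length=0.0, children=None):
        self.name = name
        self.length = length
        self.children = children or []

    def newick(self) -> str:
        def fmt(node):
            if not node.children:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def _random_clade(leaf_names: Sequence[str], scale: float,
                  rng: np.random.Generator) -> _SimNode:
    nodes = [_SimNode(name, float(rng.exponential(scale)))
             for name in leaf_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = _SimNode(None, float(rng.exponential(scale)),
                          [nodes[i], nodes[j]])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def _evolve(codes: np.ndarray, branch: float,
            rng: np.random.Generator) -> np.ndarray:
    """20-state Jukes-Cantor-like substitution along one branch."""
    p = (19.0 / 20.0) * (1.0 - math.exp(-20.0 * branch / 19.0))
    mask = rng.random(codes.size) < p
    out = codes.copy()
    shift = rng.integers(1, 20, size=int(mask.sum()))
    out[mask] = (out[mask] + shift) % 20
    return out


def _simulate_down(node: _SimNode, codes: np.ndarray,
                   rng: np.random.Generator,
                   out: dict[str, np.ndarray]) -> None:
    codes = _evolve(codes, node.length, rng)
    if not node.children:
        out[node.name] = codes
        return
    for child in node.children:
        _simulate_down(child, codes, rng, out)


@dataclass
class ReferencePanel:
    """Simulated protein families with planted transfers."""

    families: dict[str, dict[str, str]]       # family -> leaf id -> protein
    taxonomy: dict[str, str]                  # leaf id -> class
    origins: dict[str, str]                   # leaf id -> community | reference
    trees: dict[str, str]                     # family -> true tree (newick)
    truth: list[PlantedEvent]                 # grafted community leaves
    graft_distance: float


def simulate_family(fam: str, donor: str, recipient: str,
                    rng: np.random.Generator,
                    n_ref_per_class: int = 6,
                    family_length: int = 250,
                    within_scale: float = 0.08,
                    clade_separation: float = 1.0,
                    grafted: bool = False,
                    graft_distance: float = 0.1,
                    recip_leaf: Optional[str] = None,
                    donor_leaf: Optional[str] = None,
                    seed_protein: Optional[str] = None,
                    ) -> tuple[dict[str, str], list[str], list[str], str]:
    """Simulate one protein family over a two-clade class tree.

    Returns (proteins by leaf id, donor reference ids, recipient
    reference ids, true tree newick). With ``grafted`` the
    recipient-class community leaf hangs off a random donor reference at
    ``graft_distance`` instead of sitting in its own clade.

    When ``seed_protein`` is given, the family is simulated outward from
    that sequence at the community leaf (the substitution process is
    reversible, so rooting the simulation at a leaf is statistically
    equivalent); this lets an existing ORF protein anchor a family.
    """
    if seed_protein is not None and recip_leaf is None:
        raise ValueError("seed_protein requires a community leaf name")
    if grafted and recip_leaf is None:
        raise ValueError("grafted family needs a recipient leaf name")

    donor_refs = [f"{fam}_{donor[:5]}_r{i}" for i in range(n_ref_per_class)]
    recip_refs = [f"{fam}_{recipient[:5]}_r{i}"
                  for i in range(n_ref_per_class)]

    def clade_of(names, comm_leaf):
        clade = _random_clade(names, within_scale, rng)
        if comm_leaf is not None:
            target = names[int(rng.integers(0, len(names)))]
            _attach_sibling(clade, target, comm_leaf, within_scale / 2.0)
        return clade

    if seed_protein is None:
        donor_clade = clade_of(donor_refs, donor_leaf)
        recip_clade = clade_of(recip_refs,
                               None if grafted else recip_leaf)
        if grafted:
            parent = donor_refs[int(rng.integers(0, n_ref_per_class))]
            _attach_pendant(donor_clade, parent, recip_leaf, graft_distance)
        donor_clade.length = clade_separation / 2.0
        recip_clade.length = clade_separation / 2.0
        root = _SimNode(None, 0.0, [donor_clade, recip_clade])
        root_codes = rng.integers(0, 20, size=family_length)
    else:
        # root the simulation at the community leaf itself
        root_codes = np.array([_AA_INDEX[a] for a in seed_protein])
        if grafted:
            # community leaf hangs at graft_distance from donor ref r0;
            # the rest of the donor clade and the whole recipient clade
            # sit beyond it
            rest = _random_clade(donor_refs[1:], within_scale, rng)
            if donor_leaf is not None:
                target = donor_refs[1 + int(rng.integers(0,
                                            len(donor_refs) - 1))]
                _attach_sibling(rest, target, donor_leaf, within_scale / 2.0)
            far = _SimNode(None, graft_distance, [
                _SimNode(donor_refs[0], 0.0),
                rest,
                _SimNode(None, clade_separation,
                         [_random_clade(recip_refs, within_scale, rng)]),
            ])
        else:
            # community leaf sits inside its own (recipient) class clade
            rest = _random_clade(recip_refs[1:], within_scale, rng)
            far = _SimNode(None, within_scale, [
                _SimNode(recip_refs[0], 0.0),
                rest,
                _SimNode(None, clade_separation,
                         [_random_clade(donor_refs, within_scale, rng)]),
            ])
        root = _SimNode(None, 0.0, [_SimNode(recip_leaf, 0.0), far])
    seqs: dict[str, np.ndarray] = {}
    for child in root.children:
        _simulate_down(child, root_codes, rng, seqs)
    proteins = {name: "".join(_AA[c] for c in codes)
                for name, codes in seqs.items()}
    if seed_protein is None:
        proteins = {name: "M" + p[1:] for name, p in proteins.items()}
    return proteins, donor_refs, recip_refs, root.newick()


def generate_reference_panel_and_trees(
        class_labels: Sequence[str],
        n_families: int = 100,
        transfer_fraction: float = 0.1,
        seed: int = 0,
        n_ref_per_class: int = 6,
        family_length: int = 250,
        within_scale: float = 0.08,
        clade_separation: float = 1.0,
        graft_distance: float = 0.1,
        community: str = "AU",
        ) -> ReferencePanel:
    """Simulate ``n_families`` protein families over two-class trees.

    Each family has a donor-class clade and a recipient-class clade,
    ``clade_separation`` substitutions/site apart, each containing
    ``n_ref_per_class`` reference leaves plus one community leaf sitting
    inside its clade. In a ``transfer_fraction`` of families the
    recipient-class community leaf is instead grafted as a pendant of a
    random donor-clade reference leaf at ``graft_distance``.
    """
    if not (0.0 <= transfer_fraction <= 1.0):
        raise ValueError("transfer_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_transfer = int(round(transfer_fraction * n_families))
    families: dict[str, dict[str, str]] = {}
    taxonomy: dict[str, str] = {}
    origins: dict[str, str] = {}
    trees: dict[str, str] = {}
    truth: list[PlantedEvent] = []
    for fi in range(n_families):
        fam = f"F{fi:04d}"
        donor_i, recip_i = rng.choice(len(class_labels), size=2,
                                      replace=False)
        donor = class_labels[int(donor_i)]
        recip = class_labels[int(recip_i)]
        grafted = fi < n_transfer
        recip_leaf = f"{fam}_q_recip"
        donor_leaf = f"{fam}_q_donor"
        proteins, donor_refs, recip_refs, newick = simulate_family(
            fam, donor, recip, rng, n_ref_per_class, family_length,
            within_scale, clade_separation, grafted, graft_distance,
            recip_leaf, donor_leaf)
        families[fam] = proteins
        trees[fam] = newick
        for name in donor_refs:
            taxonomy[name] = donor
            origins[name] = "reference"
        for name in recip_refs:
            taxonomy[name] = recip
            origins[name] = "reference"
        taxonomy[donor_leaf] = donor
        origins[donor_leaf] = community
        taxonomy[recip_leaf] = recip
        origins[recip_leaf] = community
        if grafted:
            truth.append(PlantedEvent(
                event_id=f"{fam}_graft", donor_class=donor,
                recipient_class=recip, contig_id=".", orf_id=recip_leaf,
                start=0, end=0, strand="+"))
    return ReferencePanel(families=families, taxonomy=taxonomy,
                          origins=origins, trees=trees, truth=truth,
                          graft_distance=graft_distance)


def _attach_sibling(root: _SimNode, target_name: str, new_name: str,
                    half: float) -> None:
    """Replace leaf ``target_name`` by an internal node with the original
    leaf and ``new_name`` as children, ``half`` branch length each."""
    def walk(node):
        for idx, child in enumerate(node.children):
            if not child.children and child.name == target_name:
                node.children[idx] = _SimNode(None, child.length, [
                    _SimNode(target_name, half),
                    _SimNode(new_name, half)])
                return True
            if walk(child):
                return True
        return False
    if not walk(root):
        raise ValueError(f"leaf {target_name} not found")


def _attach_pendant(root: _SimNode, target_name: str, new_name: str,
                    distance: float) -> None:
    """Attach ``new_name`` at patristic distance ``distance`` from leaf
    ``target_name`` (the target keeps a zero-length pendant)."""
    def walk(node):
        for idx, child in enumerate(node.children):
            if not child.children and child.name == target_name:
                node.children[idx] = _SimNode(None, child.length, [
                    _SimNode(target_name, 0.0),
                    _SimNode(new_name, distance)])
                return True
            if walk(child):
                return True
        return False
    if not walk(root):
        raise ValueError(f"leaf {target_name} not found")


# ---------------------------------------------------------------------------
# Integrated community generator
# ---------------------------------------------------------------------------

# ECs cycled onto planted ORFs; backgrounds draw from the packaged table
_PLANT_ECS = ("4.2.1.17", "2.3.1.9", "2.7.1.11", "1.9.3.1", "2.7.2.3",
              "2.7.1.2", "6.3.5.4", "5.4.2.1")


@dataclass
class SyntheticCommunity:
    """A fully specified synthetic metagenome with ground truth."""

    community: str
    models: list[KmerClassModel]
    contigs: list[ContigRecord]
    orfs: list[OrfRecord]
    contig_classes: dict[str, str]          # true class per contig
    taxonomy: dict[str, str]                # reference/MGE/panel ids -> class
    orf_hits: list[AlignmentHit]
    contig_hits: list[AlignmentHit]
    mge_records: list[tuple[str, str, str]]  # (id, protein, class)
    reads: list[tuple[str, str]]
    panel: Optional[ReferencePanel]
    truth: list[PlantedEvent]

    def write(self, outdir: str | Path) -> Path:
        """Emit every pipeline input format plus truth and a manifest;
        returns the manifest path."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([(c.id, c.sequence) for c in self.contigs],
                    out / "contigs.fasta")
        write_orf_table(self.orfs, out / "orfs.tsv")
        write_fasta([(o.id, o.protein) for o in self.orfs],
                    out / "orf_proteins.fasta")
        write_taxonomy(self.taxonomy, out / "taxonomy.tsv")
        write_hit_table(self.orf_hits, out / "hits_orfs.tsv")
        write_hit_table(self.contig_hits, out / "hits_contigs.tsv")
        write_fasta([(m[0], m[1]) for m in self.mge_records],
                    out / "mge_proteins.fasta")
        write_taxonomy({m[0]: m[2] for m in self.mge_records},
                       out / "mge_taxonomy.tsv")
        write_fasta(self.reads, out / "reads.fasta")
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for m in self.models:
            m.to_json(models_dir / f"{m.class_label}.json")
        ref_proteins = {}
        if self.panel is not None:
            orf_ids = {o.id for o in self.orfs}
            for fam, prots in self.panel.families.items():
                for leaf, seq in prots.items():
                    if leaf not in orf_ids:
                        ref_proteins[leaf] = seq
        write_fasta(sorted(ref_proteins.items()),
                    out / "ref_proteins.fasta")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("event_id\tdonor\trecipient\tcontig_id\torf_id\tstart\t"
                     "end\tstrand\tec\tmge_homolog\tmobility_neighbor\n")
            for e in self.truth:
                fh.write("\t".join([
                    e.event_id, e.donor_class, e.recipient_class,
                    e.contig_id, e.orf_id, str(e.start), str(e.end),
                    e.strand, e.ec_number or ".", e.mge_homolog_id or ".",
                    str(int(e.mobility_neighbor))]) + "\n")
        manifest = {
            "community": self.community,
            "contigs": "contigs.fasta",
            "orfs": "orfs.tsv",
            "orf_proteins": "orf_proteins.fasta",
            "taxonomy": "taxonomy.tsv",
            "orf_hits": "hits_orfs.tsv",
            "contig_hits": "hits_contigs.tsv",
            "mge_proteins": "mge_proteins.fasta",
            "mge_taxonomy": "mge_taxonomy.tsv",
            "ref_proteins": "ref_proteins.fasta",
            "reads": "reads.fasta",
            "models_dir": "models",
            "truth": "truth.tsv",
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        return out / "manifest.json"


def _synthetic_hit_pair(qid: str, qlen: int, own_class: str,
                        other_class: str, genomes: Mapping[str, str],
                        rng: np.random.Generator,
                        best_exp_range: tuple[float, float],
                        gap_range: tuple[float, float] = (15.0, 30.0),
                        ) -> list[AlignmentHit]:
    """Emulated reference-database search result for one sequence: a best
    hit to its source class and a much weaker best hit from another
    class (the order-of-magnitude gap feeds confidence grouping)."""
    own_genomes = sorted(g for g, c in genomes.items() if c == own_class)
    other_genomes = sorted(g for g, c in genomes.items() if c == other_class)
    e1_exp = rng.uniform(*best_exp_range)
    gap = rng.uniform(*gap_range)
    aln = max(30, int(qlen * rng.uniform(0.8, 0.98)))
    hits = []
    for sid, e_exp in ((own_genomes[int(rng.integers(len(own_genomes)))], e1_exp),
                       (other_genomes[int(rng.integers(len(other_genomes)))],
                        e1_exp - gap)):
        hits.append(AlignmentHit(
            query_id=qid, subject_id=sid,
            pct_identity=float(rng.uniform(80, 99)), aln_len=aln,
            q_start=1, q_end=aln, s_start=1, s_end=aln,
            evalue=10.0 ** (-e_exp), bitscore=round(2.5 * e_exp, 1),
            q_len=qlen, s_len=aln))
    return hits


def generate_community(
        n_classes: int = 3,
        n_contigs: int = 12,
        n_plants: int = 4,
        contig_len_range: tuple[int, int] = (2000, 10000),
        orf_aa_range: tuple[int, int] = (120, 280),
        gap_range: tuple[int, int] = (30, 120),
        k: int = 4,
        divergence: float = 1.0,
        seed: int = 0,
        community: str = "AU",
        with_families: bool = True,
        n_background_families: Optional[int] = None,
        with_reads: bool = True,
        read_length: int = 500,
        read_depth: float = 10.0,
        plant_on_long: bool = True,
        mge_decoys: int = 5,
        mge_fraction_mobility: float = 0.5,
        n_ref_per_class: int = 6,
        within_scale: float = 0.08,
        clade_separation: float = 1.0,
        graft_distance: float = 0.1,
        ) -> SyntheticCommunity:
    """Generate a complete synthetic community with planted transfers.

    Planted ORFs are simultaneously (a) compositionally regenerated from
    the donor class's Markov chain, (b) the anchor of a simulated protein
    family in which they hang grafted inside the donor clade at
    ``graft_distance``, and (c) given a homolog in the mobile-element
    database, so that all three detection routes can fire on the same
    ground truth. Background ORFs anchor ungrafted families sitting
    inside their own class clade.
    """
    rng = np.random.default_rng(seed)
    models = sample_class_models(n_classes, k=k, divergence=divergence,
                                 seed=seed)
    labels = [m.class_label for m in models]
    by_label = {m.class_label: m for m in models}

    # reference genomes for the emulated homology searches
    genomes = {f"{cls}_genome{j}": cls for cls in labels for j in (1, 2)}
    taxonomy: dict[str, str] = dict(genomes)

    contigs: list[ContigRecord] = []
    orfs: list[OrfRecord] = []
    contig_classes: dict[str, str] = {}
    contig_orfs: dict[str, list[OrfRecord]] = {}
    for i in range(n_contigs):
        cls = labels[i % n_classes]
        length = int(rng.integers(contig_len_range[0],
                                  contig_len_range[1] + 1))
        layout = []
        pos = int(rng.integers(*gap_range))
        while True:
            aa = int(rng.integers(*orf_aa_range))
            span = 3 * (aa + 2)
            if pos + span - 1 > length - 10:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            layout.append((pos, pos + span - 1, strand))
            pos += span + int(rng.integers(*gap_range))
        cid = f"{community}_c{i + 1:03d}"
        contig, c_orfs = generate_contig(
            by_label[cls], length, layout,
            seed=int(rng.integers(0, 2 ** 31)), contig_id=cid,
            community=community)
        contigs.append(contig)
        contig_orfs[cid] = c_orfs
        contig_classes[cid] = cls

    # choose planted ORFs: one per contig, interior ORFs preferred,
    # long contigs preferred when plant_on_long
    eligible = [c for c in contigs if len(contig_orfs[c.id]) >= 2]
    if n_plants > len(eligible):
        raise ValueError(f"cannot plant {n_plants} events on "
                         f"{len(eligible)} eligible contigs")
    weights = np.array([c.length for c in eligible], dtype=float)
    if not plant_on_long:
        weights = np.ones(len(eligible))
    weights /= weights.sum()
    plant_idx = rng.choice(len(eligible), size=n_plants, replace=False,
                           p=weights)
    plant_contigs = [eligible[int(i)] for i in plant_idx]

    panel_families: dict[str, dict[str, str]] = {}
    panel_tax: dict[str, str] = {}
    panel_origins: dict[str, str] = {}
    panel_trees: dict[str, str] = {}
    truth: list[PlantedEvent] = []
    mge_records: list[tuple[str, str, str]] = []

    for ev_i, contig in enumerate(plant_contigs, start=1):
        c_orfs = contig_orfs[contig.id]
        recip_cls = contig_classes[contig.id]
        donor_cls = labels[int(rng.choice(
            [j for j, l in enumerate(labels) if l != recip_cls]))]
        # interior ORF so a mobility neighbor exists
        target = c_orfs[int(rng.integers(0, max(1, len(c_orfs) - 1)))]
        ec = _PLANT_ECS[(ev_i - 1) % len(_PLANT_ECS)]
        mobility = rng.random() < mge_fraction_mobility
        new_contig, new_orfs, event, mge = plant_lgt(
            contig, c_orfs, target.id, by_label[donor_cls],
            seed=int(rng.integers(0, 2 ** 31)), recipient_class=recip_cls,
            ec_number=ec, mge_homolog=True, mobility_neighbor=mobility,
            event_id=f"ev{ev_i}")
        idx = contigs.index(contig)
        contigs[idx] = new_contig
        contig_orfs[contig.id] = new_orfs
        truth.append(event)
        if mge is not None:
            mge_records.append(mge)
            taxonomy[mge[0]] = mge[2]
        if with_families:
            # anchor a protein family on the planted ORF's translation,
            # grafted into the donor clade
            planted_orf = next(o for o in new_orfs if o.id == target.id)
            fam = f"fam_{target.id}"
            prots, d_refs, r_refs, newick = simulate_family(
                fam, donor_cls, recip_cls, rng, n_ref_per_class,
                len(planted_orf.protein), within_scale, clade_separation,
                grafted=True, graft_distance=graft_distance,
                recip_leaf=target.id, seed_protein=planted_orf.protein)
            panel_families[fam] = prots
            panel_trees[fam] = newick
            for name in d_refs + r_refs:
                panel_tax[name] = (donor_cls if name in d_refs else recip_cls)
                panel_origins[name] = "reference"
            panel_tax[target.id] = recip_cls
            panel_origins[target.id] = community

    # background families: concordant community leaves, no graft
    planted_ids = {e.orf_id for e in truth}
    if with_families:
        background = [o for c in contigs for o in contig_orfs[c.id]
                      if o.id not in planted_ids]
        n_bg = (n_plants if n_background_families is None
                else n_background_families)
        n_bg = min(n_bg, len(background))
        for o in [background[int(i)] for i in
                  rng.choice(len(background), size=n_bg, replace=False)]:
            own_cls = contig_classes[o.contig_id]
            other = labels[int(rng.choice(
                [j for j, l in enumerate(labels) if l != own_cls]))]
            fam = f"fam_{o.id}"
            prots, d_refs, r_refs, newick = simulate_family(
                fam, other, own_cls, rng, n_ref_per_class,
                len(o.protein), within_scale, clade_separation,
                grafted=False, recip_leaf=o.id, seed_protein=o.protein)
            panel_families[fam] = prots
            panel_trees[fam] = newick
            for name in d_refs + r_refs:
                panel_tax[name] = other if name in d_refs else own_cls
                panel_origins[name] = "reference"
            panel_tax[o.id] = own_cls
            panel_origins[o.id] = community

    orfs = [o for c in contigs for o in contig_orfs[c.id]]
    # sprinkle ECs over background ORFs
    ec_pool = list(_PLANT_ECS)
    orfs = [o if (o.id in planted_ids or rng.random() > 0.3)
            else replace(o, annotation=ec_pool[int(rng.integers(len(ec_pool)))])
            for o in orfs]

    # emulated reference-search hit tables
    donor_of = {e.orf_id: e.donor_class for e in truth}
    orf_hits: list[AlignmentHit] = []
    contig_hits: list[AlignmentHit] = []
    for c in contigs:
        own = contig_classes[c.id]
        other = labels[int(rng.choice(
            [j for j, l in enumerate(labels) if l != own]))]
        contig_hits += _synthetic_hit_pair(c.id, c.length, own, other,
                                           genomes, rng, (60.0, 120.0))
    for o in orfs:
        source = donor_of.get(o.id, contig_classes[o.contig_id])
        other = labels[int(rng.choice(
            [j for j, l in enumerate(labels) if l != source]))]
        orf_hits += _synthetic_hit_pair(o.id, o.nt_length, source, other,
                                        genomes, rng, (40.0, 90.0))

    # decoy mobile-element records (random proteins, random classes)
    for d in range(mge_decoys):
        length = int(rng.integers(150, 300))
        seq = "".join(_AA[int(i)] for i in rng.integers(0, 20, size=length))
        cls = labels[int(rng.integers(0, n_classes))]
        mid = f"mge_decoy{d + 1}"
        mge_records.append((mid, "M" + seq[1:], cls))
        taxonomy[mid] = cls

    reads: list[tuple[str, str]] = []
    if with_reads:
        reads = generate_reads(contigs, read_length, read_depth,
                               seed=int(rng.integers(0, 2 ** 31)))

    panel = None
    if with_families:
        panel = ReferencePanel(
            families=panel_families, taxonomy=panel_tax,
            origins=panel_origins, trees=panel_trees,
            truth=[e for e in truth], graft_distance=graft_distance)
        taxonomy.update(panel_tax)

    return SyntheticCommunity(
        community=community, models=models, contigs=contigs, orfs=orfs,
        contig_classes=contig_classes, taxonomy=taxonomy,
        orf_hits=orf_hits, contig_hits=contig_hits,
        mge_records=mge_records, reads=reads, panel=panel, truth=truth)
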