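"""Post-detection synthesis: pathway mapping, method intersection,
directed genetic-exchange networks, mobility-gene proximity and contig
statistics.

Pathway labels cover six energy-related metabolic pathways: butanoate
metabolism (BM), citric acid cycle (CAC), glycolysis/gluconeogenesis
(GG), pentose phosphate pathway (PPP), propanoate metabolism (PM) and
nitrogen metabolism (NM).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .core_io import ContigRecord, OrfRecord
from .discordance import LgtCall
from .homology import FunctionalAnnotation

logger = logging.getLogger("lgtscan")

PATHWAY_LABELS = ("BM", "CAC", "GG", "PPP", "PM", "NM")


def load_default_pathway_table() -> dict[str, frozenset[str]]:
    """Packaged toy EC -> pathway table covering the six energy-related
    pathways."""
    from importlib import resources

    from .core_io import read_pathway_table
    with resources.as_file(resources.files("lgtscan.data")
                           / "ec_pathways.tsv") as p:
        return read_pathway_table(p)

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|n?\d*)$")

DEFAULT_MOBILITY_KEYWORDS = {"transposase": "transposase",
                             "integrase": "integrase"}


@dataclass
class ExchangeNetwork:
    """Directed transfer multigraph for one pathway in one community.

    Directed edges come from oriented (discordance) calls; undirected
    partner edges from phylogenetic calls are kept as a separate layer.
    Edge multiplicity equals the number of witness (EC, orf_id) pairs.
    """

    pathway: str
    community: str
    directed: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    undirected: nx.MultiGraph = field(default_factory=nx.MultiGraph)

    def multiplicity(self, donor: str, recipient: str) -> int:
        if self.directed.has_edge(donor, recipient):
            return self.directed.number_of_edges(donor, recipient)
        return 0


def map_ec_to_pathways(annotations: Iterable[FunctionalAnnotation],
                       pathway_table: Mapping[str, frozenset[str]],
                       ) -> dict[str, frozenset[str]]:
    """Assign ORFs to pathways via their EC numbers. ORFs with no EC, a
    malformed EC (warned) or an EC outside the table are unassigned."""
    out: dict[str, frozenset[str]] = {}
    for ann in annotations:
        if ann.ec_number is None:
            continue
        if not _EC_RE.match(ann.ec_number):
            logger.warning("malformed EC number %r for %s; unassigned",
                           ann.ec_number, ann.orf_id)
            continue
        pathways = pathway_table.get(ann.ec_number)
        if pathways:
            out[ann.orf_id] = frozenset(pathways)
    return out


def intersect_method_calls(
        discordance_calls: Sequence[LgtCall],
        phylo_calls: Sequence[LgtCall],
        mge_pass_set: Iterable[str],
        orf_pathways: Optional[Mapping[str, frozenset[str]]] = None,
        ) -> tuple[dict[str, dict[str, int]], frozenset[str]]:
    """Three-way intersection of the two analyses and the MGE screen.

    Returns (venn counts, high-confidence set). Counts are reported under
    "all" and, when ``orf_pathways`` is given, per pathway; each entry has
    discordance_only / phylo_only / both / both_mge. The high-confidence
    set is (discordance AND phylogenetic AND MGE-supported) orf ids.
    """
    d_set = {c.orf_id for c in discordance_calls}
    p_set = {c.orf_id for c in phylo_calls}
    mge = set(mge_pass_set)

    def venn(ds: set[str], ps: set[str]) -> dict[str, int]:
        both = ds & ps
        return {"discordance_only": len(ds - ps),
                "phylo_only": len(ps - ds),
                "both": len(both),
                "both_mge": len(both & mge)}

    counts = {"all": venn(d_set, p_set)}
    if orf_pathways is not None:
        for pw in PATHWAY_LABELS:
            ds = {o for o in d_set if pw in orf_pathways.get(o, ())}
            ps = {o for o in p_set if pw in orf_pathways.get(o, ())}
            counts[pw] = venn(ds, ps)
    high_confidence = frozenset(d_set & p_set & mge)
    return counts, high_confidence


def build_exchange_network(calls: Sequence[LgtCall],
                           orf_pathways: Mapping[str, frozenset[str]],
                           community: str,
                           orf_ecs: Optional[Mapping[str, str]] = None,
                           pathways: Sequence[str] = PATHWAY_LABELS,
                           ) -> list[ExchangeNetwork]:
    """One network per pathway. Oriented discordance calls add directed
    donor -> recipient edges; phylogenetic calls add undirected partner
    edges in a separate layer. Witnesses stay itemized: each call
    contributes one edge carrying its (EC, orf_id)."""
    orf_ecs = orf_ecs or {}
    nets = []
    for pw in pathways:
        net = ExchangeNetwork(pathway=pw, community=community)
        for c in sorted(calls, key=lambda c: (c.orf_id, c.method)):
            if pw not in orf_pathways.get(c.orf_id, ()):
                continue
            ec = orf_ecs.get(c.orf_id)
            if c.method == "discordance":
                if c.donor_class == c.recipient_class:
                    continue  # no self-loops
                net.directed.add_edge(c.donor_class, c.recipient_class,
                                      ec=ec, orf_id=c.orf_id)
            else:
                if c.recipient_class == c.partner_class:
                    continue
                net.undirected.add_edge(c.recipient_class, c.partner_class,
                                        ec=ec, orf_id=c.orf_id)
        nets.append(net)
    return nets


def write_network_tsv(net: ExchangeNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tcommunity\tdirected\tdonor_or_a\trecipient_or_b\t"
                 "ec\torf_id\n")
        rows = []
        for u, v, data in net.directed.edges(data=True):
            rows.append((net.pathway, net.community, "1", u, v,
                         data.get("ec") or ".", data["orf_id"]))
        for u, v, data in net.undirected.edges(data=True):
            a, b = sorted((u, v))
            rows.append((net.pathway, net.community, "0", a, b,
                         data.get("ec") or ".", data["orf_id"]))
        for row in sorted(rows):
            fh.write("\t".join(row) + "\n")


def write_network_graphml(net: ExchangeNetwork, path: str | Path) -> None:
    g = nx.MultiDiGraph()
    for u, v, data in net.directed.edges(data=True):
        g.add_edge(u, v, ec=data.get("ec") or "", orf_id=data["orf_id"],
                   directed="1")
    for u, v, data in net.undirected.edges(data=True):
        a, b = sorted((u, v))
        g.add_edge(a, b, ec=data.get("ec") or "", orf_id=data["orf_id"],
                   directed="0")
    nx.write_graphml(g, str(path))


def scan_mobility_genes(orfs: Sequence[OrfRecord],
                        keywords: Mapping[str, str] = DEFAULT_MOBILITY_KEYWORDS,
                        ) -> list[tuple[str, str]]:
    """Case-insensitive keyword scan of ORF product strings; returns
    (orf_id, category) for every match."""
    out = []
    for o in orfs:
        if not o.product:
            continue
        text = o.product.lower()
        for kw, category in keywords.items():
            if kw in text:
                out.append((o.id, category))
    return out


def flag_mobility_adjacent(calls: Sequence[LgtCall],
                           orfs: Sequence[OrfRecord],
                           keywords: Mapping[str, str] = DEFAULT_MOBILITY_KEYWORDS,
                           ) -> list[LgtCall]:
    """Return calls with mobility_adjacent set true iff the call's contig
    carries at least one transposase/integrase-annotated ORF."""
    hits = scan_mobility_genes(orfs, keywords)
    orf_contig = {o.id: o.contig_id for o in orfs}
    mobile_contigs = {orf_contig[oid] for oid, _ in hits if oid in orf_contig}
    from dataclasses import replace
    return [replace(c, mobility_adjacent=(c.contig_id in mobile_contigs))
            for c in calls]


def summarize_contig_stats(contigs: Sequence[ContigRecord],
                           orfs: Sequence[OrfRecord],
                           calls: Sequence[LgtCall],
                           orf_pathways: Optional[Mapping[str, frozenset[str]]] = None,
                           ) -> list[dict]:
    """Three rows per community: all retained contigs; contigs carrying at
    least one pathway-mapped LGT call; the subset of those that are also
    mobility-adjacent. Means are reported to 2 decimals; empty subsets
    produce rows with None markers."""
    gene_count: dict[str, int] = {}
    for o in orfs:
        gene_count[o.contig_id] = gene_count.get(o.contig_id, 0) + 1
    in_pathways = (lambda c: True) if orf_pathways is None else (
        lambda c: bool(orf_pathways.get(c.orf_id)))
    lgt_contigs = {c.contig_id for c in calls if in_pathways(c)}
    mob_contigs = {c.contig_id for c in calls
                   if in_pathways(c) and c.mobility_adjacent}

    def row(group: str, subset: Sequence[ContigRecord],
            community: str) -> dict:
        if not subset:
            return {"community": community, "group": group, "n": 0,
                    "mean_length": None, "mean_genes": None}
        return {"community": community, "group": group, "n": len(subset),
                "mean_length": round(sum(c.length for c in subset)
                                     / len(subset), 2),
                "mean_genes": round(sum(gene_count.get(c.id, 0)
                                        for c in subset) / len(subset), 2)}

    rows = []
    for community in sorted({c.community for c in contigs}):
        comm = [c for c in contigs if c.community == community]
        rows.append(row("all", comm, community))
        rows.append(row("lgt_6_pathways",
                        [c for c in comm if c.id in lgt_contigs], community))
        rows.append(row("lgt_mobility_6_pathways",
                        [c for c in comm if c.id in mob_contigs], community))
    return rows


def write_stats_tsv(rows: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("community\tgroup\tn\tmean_length\tmean_genes\n")
        for r in rows:
            ml = "" if r["mean_length"] is None else f"{r['mean_length']:.2f}"
            mg = "" if r["mean_genes"] is None else f"{r['mean_genes']:.2f}"
            fh.write(f"{r['community']}\t{r['group']}\t{r['n']}\t{ml}\t{mg}\n")


def write_venn_json(counts: Mapping[str, Mapping[str, int]],
                    path: str | Path) -> None:
    Path(path).write_text(json.dumps(counts, indent=1, sort_keys=True) + "\n")
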