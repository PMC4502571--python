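"""Homology-network clustering and patristic-distance incongruence calling.

Pipeline: admit edges between proteins that pass identity/coverage/e-value
thresholds; split the network into connected components; build a tree per
component (neighbor joining on Poisson-corrected distances, or an
externally supplied Newick); cut large trees into well-supported subtrees;
then, for every community leaf, find its nearest neighbor by patristic
distance among same-community and reference leaves. A leaf whose nearest
neighbor belongs to a different taxonomic class within the patristic
cutoff is called as a candidate transfer (undirected - tree shape alone
cannot orient the event).
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .core_io import (AlignmentHit, PhyloTree, PipelineConfig, node_support,
                      read_newick)
from .discordance import LgtCall

logger = logging.getLogger("lgtscan")

# p-distances are capped here before Poisson correction so saturated pairs
# stay finite (d = -ln(1 - 0.95) ~ 3.0 substitutions/site)
MAX_P_DISTANCE = 0.95


@dataclass(frozen=True)
class Cluster:
    members: frozenset[str]
    provenance: str = "initial_component"   # or "extracted_subtree"
    iteration: int = 0


@dataclass(frozen=True)
class NeighborReport:
    focal_id: str
    focal_class: Optional[str]
    nearest_same_community_id: Optional[str]
    nearest_same_community_distance: Optional[float]
    nearest_reference_id: Optional[str]
    nearest_reference_distance: Optional[float]
    nearest_overall_class: Optional[str]
    called: bool


# ---------------------------------------------------------------------------
# Homology network
# ---------------------------------------------------------------------------

def build_homology_graph(hits: Sequence[AlignmentHit],
                         config: Optional[PipelineConfig] = None,
                         query_lengths: Optional[Mapping[str, int]] = None,
                         ) -> nx.Graph:
    """Undirected homology network: an edge is admitted iff a hit in
    either direction has identity >= net_identity, query coverage >=
    net_coverage and e-value <= net_evalue. Duplicate qualifying hits
    keep the best (smallest) e-value. Self-hits are ignored."""
    config = config or PipelineConfig()
    g = nx.Graph()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        qlen = h.q_len if h.q_len is not None else (
            query_lengths.get(h.query_id) if query_lengths else None)
        if qlen is None:
            logger.warning("homology graph: hit %s->%s lacks query length; "
                           "skipped", h.query_id, h.subject_id)
            continue
        if h.pct_identity < config.net_identity:
            continue
        if h.aln_len / qlen < config.net_coverage:
            continue
        if h.evalue > config.net_evalue:
            continue
        u, v = h.query_id, h.subject_id
        if g.has_edge(u, v):
            if h.evalue < g[u][v]["evalue"]:
                g[u][v].update(identity=h.pct_identity,
                               coverage=h.aln_len / qlen, evalue=h.evalue)
        else:
            g.add_edge(u, v, identity=h.pct_identity,
                       coverage=h.aln_len / qlen, evalue=h.evalue)
    return g


def connected_components(graph: nx.Graph
                         ) -> tuple[list[Cluster], list[str]]:
    """Split the network into connected components. Components with at
    least two members become clusters (in decreasing size, ties by
    smallest member id); singletons are reported separately."""
    comps = [set(c) for c in nx.connected_components(graph)]
    clusters = [Cluster(frozenset(c)) for c in comps if len(c) >= 2]
    clusters.sort(key=lambda c: (-len(c.members), min(c.members)))
    singletons = sorted(m for c in comps if len(c) == 1 for m in c)
    return clusters, singletons


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------

def _mafft_align(seqs: Mapping[str, str]) -> dict[str, str]:
    if shutil.which("mafft") is None:
        raise RuntimeError(
            "sequences are not aligned (unequal lengths) and mafft is not "
            "on PATH; supply pre-aligned sequences or an external tree")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        with open(fin, "w") as fh:
            for sid in sorted(seqs):
                fh.write(f">{sid}\n{seqs[sid]}\n")
        res = subprocess.run(["mafft", "--auto", "--quiet", str(fin)],
                             capture_output=True, text=True, check=True)
    out: dict[str, str] = {}
    cur = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            cur = line[1:].split()[0]
            out[cur] = ""
        elif cur is not None:
            out[cur] += line.strip().upper()
    return out


def poisson_distance_matrix(seqs: Mapping[str, str]) -> pd.DataFrame:
    """Poisson-corrected pairwise distances d = -ln(1 - p) where p is the
    proportion of differing aligned positions (gap columns excluded).
    Sequences must be of equal (aligned) length."""
    ids = sorted(seqs)
    lengths = {len(seqs[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = np.array([list(seqs[i]) for i in ids])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        diff = arr != arr[i]
        ok = (arr != "-") & (arr[i] != "-")
        denom = ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, (diff & ok).sum(axis=1) / denom, 0.0)
        p = np.minimum(p, MAX_P_DISTANCE)
        d[i] = -np.log1p(-p)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


def _nj_newick(dm: pd.DataFrame) -> str:
    tree = nj(DistanceMatrix(dm.values, ids=list(dm.index)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0  # NJ can yield small negative estimates
    return str(tree).strip()


def _bipartitions(tree: PhyloTree, all_leaves: frozenset[str]
                  ) -> set[frozenset[str]]:
    """Canonical unrooted bipartitions (side not containing the
    lexicographically smallest leaf)."""
    anchor = min(all_leaves)
    parts = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if anchor in side:
            side = all_leaves - side
        parts.add(side)
    return parts


def build_tree(cluster_proteins: Mapping[str, str],
               method: str = "nj",
               bootstrap: int = 0,
               seed: int = 0,
               align: bool = True) -> PhyloTree:
    """Build a tree for one cluster.

    The built-in path ("nj") computes Poisson-corrected distances and a
    neighbor-joining topology; with ``bootstrap`` > 0, alignment columns
    are resampled that many times and internal nodes are labelled with
    percent support. ``method`` may also be a path to (or string of) an
    externally produced Newick tree, which is ingested unchanged.
    """
    if method != "nj":
        return read_newick(method)
    if len(cluster_proteins) < 3:
        raise ValueError("need at least 3 sequences to build a tree")
    seqs = dict(cluster_proteins)
    if len({len(s) for s in seqs.values()}) != 1:
        if not align:
            raise ValueError("sequences must be pre-aligned (equal length)")
        seqs = _mafft_align(seqs)
    dm = poisson_distance_matrix(seqs)
    tree = read_newick(_nj_newick(dm))
    if bootstrap > 0:
        ids = sorted(seqs)
        all_leaves = frozenset(ids)
        L = len(seqs[ids[0]])
        rng = np.random.default_rng(seed)
        counts: dict[frozenset[str], int] = {}
        arr = {i: np.array(list(seqs[i])) for i in ids}
        for _ in range(bootstrap):
            cols = rng.integers(0, L, size=L)
            rep = {i: "".join(arr[i][cols]) for i in ids}
            rep_tree = read_newick(_nj_newick(poisson_distance_matrix(rep)))
            for bp in _bipartitions(rep_tree, all_leaves):
                counts[bp] = counts.get(bp, 0) + 1
        anchor = min(all_leaves)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is tree.seed_node:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            key = all_leaves - side if anchor in side else side
            node.label = f"{100.0 * counts.get(key, 0) / bootstrap:.0f}"
    return tree


# ---------------------------------------------------------------------------
# Supported-subtree extraction
# ---------------------------------------------------------------------------

def extract_supported_subtrees(
        tree: PhyloTree,
        config: Optional[PipelineConfig] = None,
        rebuild: Optional[Callable[[Sequence[str]], PhyloTree]] = None,
        _iteration: int = 1,
        _max_iterations: int = 5) -> list[Cluster]:
    """Cut a tree into maximal clades with support >= ``subtree_support``
    and at most ``subtree_max_leaves`` leaves.

    Leaves not captured by any supported clade form a remainder; when a
    ``rebuild`` callback is given (members -> new tree) the remainder is
    re-built and re-cut, with the pass recorded in Cluster.iteration.
    A remainder that cannot be split further is emitted whole with a
    warning when it exceeds the cap.
    """
    config = config or PipelineConfig()
    root = tree.seed_node
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    supports = [node_support(n) for n in tree.preorder_node_iter()
                if not n.is_leaf() and n is not root]
    if n_leaves > config.subtree_max_leaves and all(s is None for s in supports):
        raise ValueError("tree has no support values; rebuild it with "
                         "bootstrap support before subtree extraction")
    provenance = ("initial_component" if _iteration == 1
                  else "extracted_subtree")
    all_members = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    if n_leaves <= config.subtree_max_leaves:
        return [Cluster(all_members, provenance, _iteration)]

    found: list[frozenset[str]] = []

    def walk(node):
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        sup = node_support(node)
        if (node is not root and len(leaves) <= config.subtree_max_leaves
                and sup is not None and sup >= config.subtree_support
                and len(leaves) >= 2):
            found.append(leaves)
            return
        for child in node.child_nodes():
            if not child.is_leaf():
                walk(child)

    walk(root)
    clusters = [Cluster(m, "extracted_subtree", _iteration) for m in found]
    remainder = all_members - frozenset().union(*found) if found else all_members
    if len(remainder) >= 2:
        # a whole-tree remainder gets one rebuild on the first pass;
        # afterwards only strictly shrinking remainders recurse
        can_recurse = (rebuild is not None and _iteration < _max_iterations
                       and (len(remainder) < n_leaves or _iteration == 1))
        if can_recurse:
            sub = rebuild(sorted(remainder))
            clusters += extract_supported_subtrees(
                sub, config, rebuild, _iteration + 1, _max_iterations)
        else:
            if len(remainder) > config.subtree_max_leaves:
                logger.warning(
                    "subtree extraction: indivisible cluster of %d leaves "
                    "exceeds the %d-leaf cap; emitted whole",
                    len(remainder), config.subtree_max_leaves)
            clusters.append(Cluster(frozenset(remainder),
                                    "extracted_subtree", _iteration))
    return clusters


# ---------------------------------------------------------------------------
# Patristic distances and incongruence calls
# ---------------------------------------------------------------------------

def patristic_distances(tree: PhyloTree) -> pd.DataFrame:
    """All-pairs patristic distances (sum of branch lengths along the
    path), as a symmetric DataFrame with zero diagonal."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=labels, columns=labels)


def call_incongruent_leaves(
        tree: PhyloTree,
        leaf_classes: Mapping[str, str],
        leaf_origin: Mapping[str, str],
        config: Optional[PipelineConfig] = None,
        orf_contigs: Optional[Mapping[str, str]] = None,
        ) -> tuple[list[LgtCall], int, list[NeighborReport]]:
    """Patristic nearest-neighbor incongruence over one tree.

    ``leaf_origin`` maps leaf id to its community label or "reference".
    For each community leaf, the nearest neighbor (smallest patristic
    distance, ties broken lexicographically) among same-community and
    reference leaves is found. An undirected call is emitted when the
    neighbor's class differs from the focal class and the distance is
    strictly below ``patristic_cutoff``. Returns (calls, count of focal
    leaves whose nearest neighbor is out-of-class but beyond the cutoff,
    per-leaf neighbor reports).
    """
    config = config or PipelineConfig()
    dmat = patristic_distances(tree)
    leaves = list(dmat.index)
    missing = [l for l in leaves if l not in leaf_classes]
    for l in missing:
        logger.warning("incongruence: leaf %s has no class label; excluded", l)
    usable = [l for l in leaves if l in leaf_classes]
    calls: list[LgtCall] = []
    reports: list[NeighborReport] = []
    over_cutoff = 0
    for focal in usable:
        origin = leaf_origin.get(focal, "reference")
        if origin == "reference":
            continue
        candidates = [l for l in usable if l != focal
                      and leaf_origin.get(l, "reference") in ("reference", origin)]
        if not candidates:
            continue
        nearest = min(candidates, key=lambda l: (dmat.at[focal, l], l))
        same_comm = [l for l in candidates
                     if leaf_origin.get(l, "reference") == origin]
        refs = [l for l in candidates
                if leaf_origin.get(l, "reference") == "reference"]
        ns = min(same_comm, key=lambda l: (dmat.at[focal, l], l)) if same_comm else None
        nr = min(refs, key=lambda l: (dmat.at[focal, l], l)) if refs else None
        d = float(dmat.at[focal, nearest])
        focal_class = leaf_classes[focal]
        neighbor_class = leaf_classes[nearest]
        called = False
        if neighbor_class != focal_class:
            if d < config.patristic_cutoff:
                called = True
                calls.append(LgtCall(
                    orf_id=focal,
                    contig_id=(orf_contigs or {}).get(focal, "."),
                    method="phylogenetic",
                    recipient_class=focal_class,
                    partner_class=neighbor_class,
                    patristic_distance=d))
            else:
                over_cutoff += 1
        reports.append(NeighborReport(
            focal_id=focal, focal_class=focal_class,
            nearest_same_community_id=ns,
            nearest_same_community_distance=(
                float(dmat.at[focal, ns]) if ns else None),
            nearest_reference_id=nr,
            nearest_reference_distance=(
                float(dmat.at[focal, nr]) if nr else None),
            nearest_overall_class=neighbor_class, called=called))
    return calls, over_cutoff, reports


def write_neighbor_reports_tsv(reports: Sequence[NeighborReport],
                               path: str | Path) -> None:
    def fmt(x):
        if x is None:
            return "."
        return f"{x:.4f}" if isinstance(x, float) else str(x)

    with open(path, "w") as fh:
        fh.write("focal\tfocal_class\tnearest_same_community\tdist_same\t"
                 "nearest_reference\tdist_ref\tnearest_class\tcalled\n")
        for r in sorted(reports, key=lambda r: r.focal_id):
            fh.write("\t".join([
                r.focal_id, fmt(r.focal_class),
                fmt(r.nearest_same_community_id),
                fmt(r.nearest_same_community_distance),
                fmt(r.nearest_reference_id),
                fmt(r.nearest_reference_distance),
                fmt(r.nearest_overall_class), str(int(r.called))]) + "\n")
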