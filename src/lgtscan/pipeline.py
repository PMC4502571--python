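"""End-to-end orchestration: classify -> discordance; cluster -> trees ->
incongruence; MGE filter -> intersection -> networks -> stats -> read
validation.

Stages form a DAG executed in a fixed order; every stage logs its counts
in "in -> retained -> called" form and writes its artifacts into the
output directory. A stage failure preserves the partial outputs and the
per-stage status file. Runs are deterministic given the seed and inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

from . import composition as comp
from . import discordance as disc
from . import exchange as exch
from . import homology as hom
from . import incongruence as inc
from .core_io import (AlignmentHit, ContigRecord, OrfRecord, PipelineConfig,
                      filter_contigs_by_length, read_contigs, read_fasta,
                      read_hit_table, read_newick, read_orf_table,
                      read_reads, read_taxonomy, validate_orfs)

logger = logging.getLogger("lgtscan")

STAGES = ("load", "classify", "discordance", "cluster", "phylo", "mge",
          "intersect", "network", "stats", "validate_reads")


def _orf_nt(orf: OrfRecord, contig_seq: str) -> str:
    """Coding-strand nucleotide sequence of an ORF (1-based inclusive
    coordinates on the contig)."""
    sub = contig_seq[orf.start - 1:orf.end]
    return sub if orf.strand == "+" else comp.reverse_complement(sub)


class PipelineRun:
    """One pipeline execution over a manifest directory."""

    def __init__(self, config: PipelineConfig, manifest_path: str | Path,
                 outdir: str | Path, seed: int = 0,
                 adapter_hits: Optional[str | Path] = None,
                 adapter_trees: Optional[str | Path] = None,
                 bootstrap: int = 0):
        self.config = config
        self.manifest_path = Path(manifest_path)
        self.base = self.manifest_path.parent
        self.out = Path(outdir)
        self.seed = seed
        self.adapter_hits = adapter_hits
        self.adapter_trees = adapter_trees
        self.bootstrap = bootstrap
        self.status: dict[str, str] = {}
        manifest = json.loads(self.manifest_path.read_text())
        required = ("community", "contigs", "orfs", "orf_proteins",
                    "taxonomy", "orf_hits", "contig_hits", "mge_proteins",
                    "mge_taxonomy", "ref_proteins", "models_dir")
        missing = [k for k in required if k not in manifest]
        if missing:
            raise ValueError(f"manifest missing keys: {missing}")
        for key in required[1:]:
            if not (self.base / manifest[key]).exists():
                raise FileNotFoundError(
                    f"manifest input {key} not found: {manifest[key]}")
        self.manifest = manifest

    # -- stage: load --------------------------------------------------------
    def load(self) -> None:
        m, base = self.manifest, self.base
        self.community = m["community"]
        contigs = read_contigs(base / m["contigs"], self.community)
        proteins = dict(read_fasta(base / m["orf_proteins"]))
        orfs = read_orf_table(base / m["orfs"], proteins)
        validate_orfs(orfs, contigs)
        self.taxonomy = read_taxonomy(base / m["taxonomy"])
        self.all_contigs = contigs
        self.contigs = filter_contigs_by_length(contigs,
                                                self.config.min_contig_len)
        kept = {c.id: c.sequence for c in self.contigs}
        self.orfs = [o for o in orfs if o.contig_id in kept]
        self.orf_by_id = {o.id: o for o in self.orfs}
        self.contig_seq = kept
        self.orf_hits = read_hit_table(base / m["orf_hits"], self.taxonomy)
        self.contig_hits = read_hit_table(base / m["contig_hits"],
                                          self.taxonomy)
        self.mge_proteins = dict(read_fasta(base / m["mge_proteins"]))
        self.mge_taxonomy = read_taxonomy(base / m["mge_taxonomy"])
        self.ref_proteins = dict(read_fasta(base / m["ref_proteins"]))
        self.reads = (read_reads(base / m["reads"])
                      if m.get("reads") else [])
        models_dir = base / m["models_dir"]
        self.models = [comp.KmerClassModel.from_json(p)
                       for p in sorted(models_dir.glob("*.json"))]
        if len(self.models) < 2:
            raise ValueError(f"need >= 2 class models in {models_dir}")
        logger.info("load: %d contigs in -> %d retained (>= %d nt); "
                    "%d ORFs retained", len(contigs), len(self.contigs),
                    self.config.min_contig_len, len(self.orfs))

    # -- stage: classify ----------------------------------------------------
    def classify(self) -> None:
        hits_by_query: dict[str, list[AlignmentHit]] = {}
        for h in self.contig_hits + self.orf_hits:
            hits_by_query.setdefault(h.query_id, []).append(h)

        def predict(seq_id: str, seq: str, both: bool) -> comp.ClassPrediction:
            sv = comp.classify_composition(self.models, seq, seq_id,
                                           both_strands=both)
            best, other = comp.best_hits_by_class(
                hits_by_query.get(seq_id, []))
            return comp.assign_confidence_group(best, other, sv, self.config)

        self.contig_preds = {
            c.id: predict(c.id, c.sequence, True) for c in self.contigs}
        self.orf_preds = [
            predict(o.id, _orf_nt(o, self.contig_seq[o.contig_id]), False)
            for o in self.orfs]
        self.orf_class = {p.sequence_id: p.predicted_class
                          for p in self.orf_preds}
        n_acc = sum(1 for p in self.orf_preds
                    if p.confidence_group in disc.ELIGIBLE_GROUPS)
        logger.info("classify: %d ORFs in -> %d in groups I-II",
                    len(self.orf_preds), n_acc)
        comp.write_predictions_tsv(sorted(self.contig_preds.values(),
                                          key=lambda p: p.sequence_id),
                                   self.out / "contig_predictions.tsv")
        comp.write_predictions_tsv(self.orf_preds,
                                   self.out / "orf_predictions.tsv")

    # -- stage: discordance -------------------------------------------------
    def discordance(self) -> None:
        self.disc_calls = disc.call_discordant_orfs(
            self.contig_preds, self.orf_preds, self.orf_by_id, self.config)
        logger.info("discordance: %d ORFs in -> %d called",
                    len(self.orf_preds), len(self.disc_calls))
        disc.write_calls_tsv(self.disc_calls,
                             self.out / "discordance_calls.tsv")

    # -- stage: cluster -----------------------------------------------------
    def cluster(self) -> None:
        seqs = {o.id: o.protein for o in self.orfs if o.protein}
        seqs.update(self.ref_proteins)
        self.phylo_seqs = seqs
        if self.adapter_hits is not None:
            hits = read_hit_table(self.adapter_hits)
        else:
            hits = hom.all_vs_all_hits(seqs)
        lengths = {sid: len(s) for sid, s in seqs.items()}
        graph = inc.build_homology_graph(hits, self.config, lengths)
        self.clusters, self.singletons = inc.connected_components(graph)
        logger.info("cluster: %d sequences in -> %d clusters "
                    "(%d singletons)", len(seqs), len(self.clusters),
                    len(self.singletons))
        with open(self.out / "clusters.tsv", "w") as fh:
            fh.write("cluster\tmember\n")
            for i, c in enumerate(self.clusters, start=1):
                for mem in sorted(c.members):
                    fh.write(f"cluster{i}\t{mem}\n")

    # -- stage: phylo (trees + incongruence) --------------------------------
    def phylo(self) -> None:
        orf_ids = set(self.orf_by_id)
        leaf_classes = dict(self.taxonomy)
        for o in self.orfs:
            cp = self.contig_preds.get(o.contig_id)
            if cp is not None:
                leaf_classes[o.id] = cp.predicted_class
        leaf_origin = {sid: (self.community if sid in orf_ids
                             else "reference")
                       for sid in self.phylo_seqs}
        orf_contigs = {o.id: o.contig_id for o in self.orfs}

        trees: list[inc.PhyloTree] = []
        if self.adapter_trees is not None:
            for line in Path(self.adapter_trees).read_text().splitlines():
                if line.strip():
                    trees.append(read_newick(line))
        else:
            for ci, clus in enumerate(self.clusters):
                members = sorted(clus.members)
                if len(members) < 3:
                    continue
                sub = {mid: self.phylo_seqs[mid] for mid in members}
                boot = (self.bootstrap or 100
                        if len(members) > self.config.subtree_max_leaves
                        else self.bootstrap)
                tree = inc.build_tree(sub, bootstrap=boot,
                                      seed=self.seed + ci)
                if len(members) > self.config.subtree_max_leaves:
                    def rebuild(ids, _ci=ci):
                        return inc.build_tree(
                            {i: self.phylo_seqs[i] for i in ids},
                            bootstrap=self.bootstrap or 100,
                            seed=self.seed + _ci + 7)
                    subclusters = inc.extract_supported_subtrees(
                        tree, self.config, rebuild)
                    for sc in subclusters:
                        if len(sc.members) >= 3:
                            trees.append(inc.build_tree(
                                {i: self.phylo_seqs[i]
                                 for i in sorted(sc.members)},
                                seed=self.seed + ci))
                else:
                    trees.append(tree)
        self.trees = trees
        calls: list[disc.LgtCall] = []
        reports = []
        over = 0
        for tree in trees:
            c, o, r = inc.call_incongruent_leaves(
                tree, leaf_classes, leaf_origin, self.config, orf_contigs)
            calls += c
            over += o
            reports += r
        # only community ORFs can be calls (adapter trees may carry others)
        self.phylo_calls = [c for c in calls if c.orf_id in orf_ids]
        self.over_cutoff = over
        n_comm = sum(1 for r in reports)
        logger.info("phylo: %d trees, %d community leaves in -> %d called "
                    "(%d out-of-class beyond cutoff)", len(trees), n_comm,
                    len(self.phylo_calls), over)
        with open(self.out / "trees.nwk", "w") as fh:
            for t in trees:
                from .core_io import write_newick
                fh.write(write_newick(t))
        disc.write_calls_tsv(self.phylo_calls, self.out / "phylo_calls.tsv")
        inc.write_neighbor_reports_tsv(reports,
                                       self.out / "neighbor_reports.tsv")

    # -- stage: mge ---------------------------------------------------------
    def mge(self) -> None:
        candidates = sorted({c.orf_id for c in self.disc_calls}
                            | {c.orf_id for c in self.phylo_calls})
        mge_hits: list[AlignmentHit] = []
        mge_kmers = {mid: {s[i:i + 6] for i in range(len(s) - 5)}
                     for mid, s in self.mge_proteins.items()}
        for oid in candidates:
            protein = self.orf_by_id[oid].protein
            if not protein:
                continue
            okmers = {protein[i:i + 6] for i in range(len(protein) - 5)}
            for mid in sorted(self.mge_proteins):
                if not (okmers & mge_kmers[mid]):
                    continue
                hit = hom.local_align(protein, self.mge_proteins[mid],
                                      oid, mid, nucleotide=False)
                if hit is not None:
                    mge_hits.append(replace(
                        hit, subject_class=self.mge_taxonomy.get(mid)))
        self.mge_pass = set(hom.mge_homology_filter(
            candidates, mge_hits, self.orf_class, self.config))
        logger.info("mge: %d candidates in -> %d MGE-supported",
                    len(candidates), len(self.mge_pass))
        self.disc_calls = [replace(c, mge_supported=c.orf_id in self.mge_pass)
                           for c in self.disc_calls]
        self.phylo_calls = [replace(c, mge_supported=c.orf_id in self.mge_pass)
                            for c in self.phylo_calls]
        with open(self.out / "mge_pass.tsv", "w") as fh:
            fh.write("orf_id\n")
            for oid in sorted(self.mge_pass):
                fh.write(oid + "\n")

    # -- stage: intersect ---------------------------------------------------
    def intersect(self) -> None:
        annotations = [hom.FunctionalAnnotation(
            orf_id=o.id, reference_id=".", ec_number=o.annotation,
            pct_query_aligned=1.0, evalue=0.0, len_ratio=1.0)
            for o in self.orfs if o.annotation]
        table = exch.load_default_pathway_table()
        self.orf_pathways = exch.map_ec_to_pathways(annotations, table)
        self.orf_ecs = {o.id: o.annotation for o in self.orfs
                        if o.annotation}
        self.venn, self.high_confidence = exch.intersect_method_calls(
            self.disc_calls, self.phylo_calls, self.mge_pass,
            self.orf_pathways)
        logger.info("intersect: %d + %d calls in -> %d high-confidence",
                    len(self.disc_calls), len(self.phylo_calls),
                    len(self.high_confidence))
        exch.write_venn_json(self.venn, self.out / "venn.json")
        donor = {c.orf_id: c for c in self.disc_calls}
        partner = {c.orf_id: c for c in self.phylo_calls}
        with open(self.out / "high_confidence.tsv", "w") as fh:
            fh.write("orf_id\tcontig_id\tdonor\trecipient\tpartner\tec\n")
            for oid in sorted(self.high_confidence):
                d = donor[oid]
                p = partner[oid]
                fh.write("\t".join([
                    oid, d.contig_id, d.donor_class, d.recipient_class,
                    p.partner_class, self.orf_ecs.get(oid, ".")]) + "\n")

    # -- stage: network -----------------------------------------------------
    def network(self) -> None:
        mobile = exch.flag_mobility_adjacent(
            self.disc_calls + self.phylo_calls, self.orfs)
        self.all_calls = mobile
        nets = exch.build_exchange_network(
            mobile, self.orf_pathways, self.community, self.orf_ecs)
        netdir = self.out / "networks"
        netdir.mkdir(exist_ok=True)
        for net in nets:
            exch.write_network_tsv(net, netdir / f"{net.pathway}.tsv")
            exch.write_network_graphml(net, netdir / f"{net.pathway}.graphml")
        logger.info("network: %d calls in -> %d pathway networks",
                    len(mobile), len(nets))

    # -- stage: stats -------------------------------------------------------
    def stats(self) -> None:
        rows = exch.summarize_contig_stats(self.contigs, self.orfs,
                                           self.all_calls,
                                           self.orf_pathways)
        exch.write_stats_tsv(rows, self.out / "contig_stats.tsv")
        logger.info("stats: %d contigs in -> %d summary rows",
                    len(self.contigs), len(rows))

    # -- stage: validate_reads ---------------------------------------------
    def validate_reads(self) -> None:
        targets = sorted({c.contig_id for c in self.all_calls
                          if c.orf_id in self.high_confidence}
                         or {c.contig_id for c in self.all_calls})
        target_contigs = [(cid, self.contig_seq[cid]) for cid in targets
                          if cid in self.contig_seq]
        reads = _prefilter_reads(self.reads, target_contigs)
        mapped = hom.map_reads_to_contigs(reads, target_contigs, self.config,
                                          seed_kmer=16)
        rows = []
        for call in sorted(self.all_calls, key=lambda c: c.orf_id):
            if call.contig_id not in dict(target_contigs):
                continue
            orf = self.orf_by_id.get(call.orf_id)
            if orf is None:
                continue
            neighbors = [o for o in self.orfs
                         if o.contig_id == orf.contig_id and o.id != orf.id]
            for ev in hom.classify_read_spans(mapped, orf, neighbors):
                rows.append(ev)
        with open(self.out / "read_validation.tsv", "w") as fh:
            fh.write("read_id\tcontig_id\torf_id\tspan_class\n")
            seen = set()
            for ev in sorted(rows, key=lambda e: (e.orf_id, e.read_id)):
                key = (ev.read_id, ev.orf_id)
                if key in seen:
                    continue
                seen.add(key)
                fh.write(f"{ev.read_id}\t{ev.contig_id}\t{ev.orf_id}\t"
                         f"{ev.span_class}\n")
        logger.info("validate_reads: %d reads in -> %d mapped -> %d span "
                    "records", len(reads), len(mapped), len(rows))

    # -----------------------------------------------------------------------
    def run(self, upto: str = "validate_reads") -> None:
        self.out.mkdir(parents=True, exist_ok=True)
        last = STAGES.index(upto)
        try:
            for stage in STAGES[:last + 1]:
                getattr(self, stage)()
                self.status[stage] = "ok"
        except Exception as exc:
            self.status[stage] = f"failed: {exc}"
            raise
        finally:
            (self.out / "status.json").write_text(
                json.dumps(self.status, indent=1) + "\n")


def _prefilter_reads(reads: Sequence[tuple[str, str]],
                     contigs: Sequence[tuple[str, str]],
                     kmer: int = 16) -> list[tuple[str, str]]:
    """Keep reads sharing an exact k-mer (either strand) with a target
    contig; avoids quadratic alignment over off-target reads."""
    index: set[str] = set()
    for _, seq in contigs:
        for i in range(len(seq) - kmer + 1):
            index.add(seq[i:i + kmer])
    out = []
    for rid, seq in reads:
        rc = comp.reverse_complement(seq)
        if any(seq[i:i + kmer] in index
               for i in range(0, len(seq) - kmer + 1, kmer)) or \
           any(rc[i:i + kmer] in index
               for i in range(0, len(rc) - kmer + 1, kmer)):
            out.append((rid, seq))
    return out


def run_pipeline(config: PipelineConfig, manifest_path: str | Path,
                 outdir: str | Path, seed: int = 0,
                 upto: str = "validate_reads",
                 adapter_hits: Optional[str | Path] = None,
                 adapter_trees: Optional[str | Path] = None) -> PipelineRun:
    """Execute the pipeline over a manifest directory and return the run
    object (artifacts are written to ``outdir``)."""
    run = PipelineRun(config, manifest_path, outdir, seed,
                      adapter_hits, adapter_trees)
    run.run(upto)
    return run
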