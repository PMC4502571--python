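"""Classification-discordance LGT calling.

A transfer is called when an ORF's class-level classification disagrees
with its parent contig's, the ORF's classification is a high-confidence
one (group I or II), and the ORF's composition likelihood under its own
class beats the likelihood under the contig's class by at least the
configured relative margin. The transfer is oriented: donor is the ORF's
class, recipient is the contig's class.

The improvement is computed on mean per-base log-likelihoods as
(s_orf_class - s_contig_class) / |s_contig_class|, a scale-free and
sign-safe margin for negative log-likelihoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .composition import ClassPrediction, ClassScoreVector
from .core_io import ContigRecord, OrfRecord, PipelineConfig

logger = logging.getLogger("lgtscan")

ELIGIBLE_GROUPS = ("I", "II")


@dataclass(frozen=True)
class LgtCall:
    """One candidate lateral transfer.

    Discordance calls are oriented (donor and recipient set); phylogenetic
    calls are undirected and carry the partner class instead of a donor.
    """

    orf_id: str
    contig_id: str
    method: str                      # "discordance" | "phylogenetic"
    donor_class: Optional[str] = None
    recipient_class: Optional[str] = None
    partner_class: Optional[str] = None
    nb_improvement: Optional[float] = None
    patristic_distance: Optional[float] = None
    orf_group: Optional[str] = None
    contig_group: Optional[str] = None
    mge_supported: bool = False
    mobility_adjacent: bool = False

    def __post_init__(self):
        if self.method == "discordance":
            if (self.donor_class is None or self.recipient_class is None
                    or self.donor_class == self.recipient_class):
                raise ValueError(
                    "discordance call needs donor != recipient classes")
        elif self.method == "phylogenetic":
            if self.partner_class is None:
                raise ValueError("phylogenetic call needs a partner class")
        else:
            raise ValueError(f"unknown method {self.method!r}")


def call_discordant_orfs(
        contig_preds: Mapping[str, ClassPrediction],
        orf_preds: Sequence[ClassPrediction],
        orfs: Mapping[str, OrfRecord],
        config: Optional[PipelineConfig] = None) -> list[LgtCall]:
    """Emit one call per eligible ORF whose class differs from its
    contig's and whose composition score under its own class is at least
    ``nb_improvement`` relatively better than under the contig's class.

    ``contig_preds`` maps contig id to the contig's prediction (any
    confidence group); only ORF predictions in groups I-II are eligible.
    ORFs shorter than 3 * kmer_order nt are never called (insufficient
    composition signal).
    """
    config = config or PipelineConfig()
    calls = []
    for pred in orf_preds:
        if pred.confidence_group not in ELIGIBLE_GROUPS:
            continue
        orf = orfs.get(pred.sequence_id)
        if orf is None:
            logger.warning("discordance: no ORF record for %s; skipped",
                           pred.sequence_id)
            continue
        if orf.nt_length < 3 * config.kmer_order:
            continue
        cpred = contig_preds.get(orf.contig_id)
        if cpred is None:
            continue
        orf_class = pred.predicted_class
        contig_class = cpred.predicted_class
        if orf_class == contig_class:
            continue
        sv = pred.composition_scores
        if sv is None or contig_class not in sv.scores or orf_class not in sv.scores:
            logger.warning("discordance: ORF %s score vector lacks class "
                           "%s or %s; skipped", pred.sequence_id,
                           orf_class, contig_class)
            continue
        s_orf = sv.scores[orf_class]
        s_contig = sv.scores[contig_class]
        if s_contig == 0.0:
            logger.warning("discordance: zero contig-class score for %s; "
                           "skipped", pred.sequence_id)
            continue
        improvement = (s_orf - s_contig) / abs(s_contig)
        if improvement < config.nb_improvement:
            continue
        calls.append(LgtCall(
            orf_id=orf.id, contig_id=orf.contig_id, method="discordance",
            donor_class=orf_class, recipient_class=contig_class,
            nb_improvement=improvement,
            orf_group=pred.confidence_group,
            contig_group=cpred.confidence_group))
    return calls


def contig_mosaic(contig: ContigRecord, orfs: Sequence[OrfRecord],
                  orf_preds: Mapping[str, ClassPrediction],
                  ) -> list[tuple[int, int, str, Optional[str]]]:
    """Per-gene class track for one contig, suitable for rendering gene
    mosaics: ordered (start, end, label, orf_id) blocks with intergenic
    gaps labelled "intergenic". Overlapping ORFs are both reported with an
    "overlap:" prefix on the later one.
    """
    own = sorted((o for o in orfs if o.contig_id == contig.id),
                 key=lambda o: (o.start, o.end, o.id))
    blocks: list[tuple[int, int, str, Optional[str]]] = []
    cursor = 1  # 1-based position of the first not-yet-covered nt
    prev_end = 0
    for o in own:
        label = (orf_preds[o.id].predicted_class
                 if o.id in orf_preds else "unclassified")
        if o.start > cursor:
            blocks.append((cursor, o.start - 1, "intergenic", None))
        if o.start <= prev_end:
            label = "overlap:" + label
        blocks.append((o.start, o.end, label, o.id))
        cursor = max(cursor, o.end + 1)
        prev_end = max(prev_end, o.end)
    if cursor <= contig.length:
        blocks.append((cursor, contig.length, "intergenic", None))
    if not own:
        return [(1, contig.length, "intergenic", None)]
    return blocks


def write_calls_tsv(calls: Sequence[LgtCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("orf_id\tcontig_id\tmethod\tdonor\trecipient\tpartner\t"
                 "improvement\tpatristic\torf_group\tcontig_group\t"
                 "mge_supported\tmobility_adjacent\n")
        for c in sorted(calls, key=lambda c: (c.orf_id, c.method)):
            fh.write("\t".join([
                c.orf_id, c.contig_id, c.method,
                c.donor_class or ".", c.recipient_class or ".",
                c.partner_class or ".",
                f"{c.nb_improvement:.4f}" if c.nb_improvement is not None else ".",
                f"{c.patristic_distance:.4f}"
                if c.patristic_distance is not None else ".",
                c.orf_group or ".", c.contig_group or ".",
                str(int(c.mge_supported)), str(int(c.mobility_adjacent)),
            ]) + "\n")
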