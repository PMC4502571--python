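"""k-mer naive-Bayes compositional classification of contigs and ORFs.

The class model is a (k-1)-order Markov chain over nucleotides: the
probability of each base is conditioned on the preceding k-1 bases, with
Laplace smoothing. A sequence score is the mean per-base natural-log
likelihood over the positions that have a full, N-free k-mer context.

Classification confidence is tiered into four groups combining homology
and composition evidence:

  I   homology and composition agree on the class;
  II  the best homology e-value is at least `group2_order_gap` orders of
      magnitude smaller than the best hit from any other class;
  III the best total NB likelihood is at least `group3_ratio` times the
      runner-up class's (a difference of ln(ratio) in total log-likelihood);
  IV  best NB likelihood only.

Groups are evaluated in order I -> II -> III -> IV and the first satisfied
group is assigned. The predicted class is the homology class for groups
I-II and the composition-best class for III-IV.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core_io import AlignmentHit, PipelineConfig

logger = logging.getLogger("lgtscan")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# floor for zero e-values in order-of-magnitude arithmetic
EVALUE_FLOOR = 1e-200


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes; non-ACGT (N) becomes -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


@dataclass
class KmerClassModel:
    """Conditional base probabilities for one taxonomic class.

    ``log_probs`` has shape (4**(k-1), 4): row = encoded k-1 context,
    column = next base. Rows for contexts never seen in training fall back
    to the Laplace limit (uniform when pseudocount > 0).
    """

    class_label: str
    k: int
    log_probs: np.ndarray
    pseudocount: float = 1.0

    @property
    def n_contexts(self) -> int:
        return 4 ** (self.k - 1)

    def prob(self, context: str, base: str) -> float:
        """Conditional probability P(base | context); context length k-1."""
        if len(context) != self.k - 1:
            raise ValueError(f"context must have length {self.k - 1}")
        idx = 0
        for c in context:
            idx = idx * 4 + _BASE_INDEX[c]
        return float(np.exp(self.log_probs[idx, _BASE_INDEX[base]]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "class_label": self.class_label,
            "k": self.k,
            "pseudocount": self.pseudocount,
            "log_probs": self.log_probs.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "KmerClassModel":
        d = json.loads(Path(path).read_text())
        return cls(class_label=d["class_label"], k=d["k"],
                   pseudocount=d["pseudocount"],
                   log_probs=np.asarray(d["log_probs"], dtype=float))


@dataclass
class ClassScoreVector:
    """Mean per-base log-likelihood of one sequence under each class model."""

    sequence_id: str
    scores: dict[str, float]          # class -> mean per-base ln-likelihood
    n_scored: dict[str, int] = field(default_factory=dict)  # positions used

    def __post_init__(self):
        if not self.scores:
            raise ValueError("ClassScoreVector requires at least one class")
        for cls_name, s in self.scores.items():
            if not math.isfinite(s):
                raise ValueError(f"non-finite score for class {cls_name}")

    def total(self, class_label: str) -> float:
        """Total log-likelihood (mean x scored positions)."""
        return self.scores[class_label] * self.n_scored.get(class_label, 1)

    @property
    def best_class(self) -> str:
        """Argmax class; ties broken lexicographically with a warning."""
        best = max(self.scores.values())
        tied = sorted(c for c, s in self.scores.items() if s == best)
        if len(tied) > 1:
            logger.warning("composition tie for %s between %s; keeping %s",
                           self.sequence_id, tied, tied[0])
        return tied[0]

    @property
    def runner_up_class(self) -> Optional[str]:
        best = self.best_class
        rest = {c: s for c, s in self.scores.items() if c != best}
        if not rest:
            return None
        top = max(rest.values())
        return sorted(c for c, s in rest.items() if s == top)[0]


@dataclass(frozen=True)
class ClassPrediction:
    sequence_id: str
    predicted_class: str
    confidence_group: str             # "I" | "II" | "III" | "IV"
    homology_class: Optional[str] = None
    homology_evalue: Optional[float] = None
    composition_scores: Optional[ClassScoreVector] = None


# ---------------------------------------------------------------------------
# Training and scoring
# ---------------------------------------------------------------------------

def train_class_model(training_sequences: Iterable[str], class_label: str,
                      k: int = 4, pseudocount: float = 1.0) -> KmerClassModel:
    """Train a (k-1)-order Markov model on both strands of the input.

    Conditional probabilities are (count + pseudocount) /
    (context_total + 4 * pseudocount).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = [s.upper() for s in training_sequences]
    if sum(len(s) for s in seqs) == 0:
        raise ValueError("empty training set")
    n_ctx = 4 ** (k - 1)
    counts = np.zeros((n_ctx, 4), dtype=float)
    for seq in seqs:
        for strand_seq in (seq, reverse_complement(seq)):
            codes = _encode(strand_seq)
            _count_kmers(codes, k, counts)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = (counts + pseudocount) / (totals + 4.0 * pseudocount)
        # contexts with no data and no smoothing: leave probability zero
        probs = np.where(totals + 4.0 * pseudocount > 0, probs, 0.0)
        log_probs = np.log(probs)
    return KmerClassModel(class_label=class_label, k=k,
                          log_probs=log_probs, pseudocount=pseudocount)


def _count_kmers(codes: np.ndarray, k: int, counts: np.ndarray) -> None:
    """Accumulate k-mer counts from encoded sequence, skipping windows
    containing N (code -1)."""
    L = codes.size
    if L < k:
        return
    valid = codes >= 0
    if k == 1:
        ok = valid
        ctx = np.zeros(L, dtype=np.int64)
        base = codes
    else:
        # rolling context code over k-1 bases ending just before position i
        n = L - k + 1
        ctx = np.zeros(n, dtype=np.int64)
        ok = np.ones(n, dtype=bool)
        for j in range(k - 1):
            ctx = ctx * 4 + np.where(valid[j:j + n], codes[j:j + n], 0)
            ok &= valid[j:j + n]
        base = codes[k - 1:]
        ok &= valid[k - 1:]
    np.add.at(counts, (ctx[ok], base[ok]), 1.0)


def _score_totals(model: KmerClassModel, seq: str) -> tuple[float, int]:
    """(total ln-likelihood, number of scored positions) for one strand."""
    codes = _encode(seq.upper())
    L = codes.size
    k = model.k
    if L < k:
        raise ValueError(f"sequence shorter than k={k}")
    n = L - k + 1
    ctx = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    valid = codes >= 0
    for j in range(k - 1):
        ctx = ctx * 4 + np.where(valid[j:j + n], codes[j:j + n], 0)
        ok &= valid[j:j + n]
    base = codes[k - 1:]
    ok &= valid[k - 1:]
    if not ok.any():
        raise ValueError("no N-free k-mer windows to score")
    ll = model.log_probs[ctx[ok], base[ok]]
    return float(ll.sum()), int(ok.sum())


def score_sequence(model: KmerClassModel, sequence: str) -> float:
    """Mean per-base ln-likelihood of ``sequence`` under ``model``.

    Positions whose k-mer window contains N are skipped; the first k-1
    positions have no full context and are not scored.
    """
    total, n = _score_totals(model, sequence)
    return total / n


def classify_composition(models: Sequence[KmerClassModel], sequence: str,
                         sequence_id: str = "",
                         both_strands: bool = False) -> ClassScoreVector:
    """Score a sequence under every class model.

    With ``both_strands`` (unoriented contigs) the better of the forward
    and reverse-complement scores is kept per class; ORFs are scored on
    their coding strand only.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 class models")
    scores: dict[str, float] = {}
    n_scored: dict[str, int] = {}
    rc = reverse_complement(sequence) if both_strands else None
    for model in models:
        total, n = _score_totals(model, sequence)
        mean = total / n
        if rc is not None:
            total_rc, n_rc = _score_totals(model, rc)
            if total_rc / n_rc > mean:
                mean, n = total_rc / n_rc, n_rc
        scores[model.class_label] = mean
        n_scored[model.class_label] = n
    return ClassScoreVector(sequence_id=sequence_id, scores=scores,
                            n_scored=n_scored)


# ---------------------------------------------------------------------------
# Confidence groups
# ---------------------------------------------------------------------------

def assign_confidence_group(
        homology_best_hit: Optional[AlignmentHit],
        homology_best_other_class_hit: Optional[AlignmentHit],
        score_vector: ClassScoreVector,
        config: Optional[PipelineConfig] = None) -> ClassPrediction:
    """Assign a sequence to confidence group I, II, III or IV.

    ``homology_best_hit`` is the overall best homology hit (its
    subject_class is the homology class); ``homology_best_other_class_hit``
    is the best hit whose subject belongs to any other class. Zero
    e-values are floored at 1e-200 for order-of-magnitude arithmetic.
    """
    config = config or PipelineConfig()
    comp_best = score_vector.best_class
    hom_class = (homology_best_hit.subject_class
                 if homology_best_hit is not None else None)
    hom_e = homology_best_hit.evalue if homology_best_hit is not None else None

    # Group I: homology and composition agree
    if hom_class is not None and hom_class == comp_best:
        return ClassPrediction(score_vector.sequence_id, hom_class, "I",
                               hom_class, hom_e, score_vector)
    # Group II: best e-value >= gap orders of magnitude below other classes
    if hom_class is not None and homology_best_other_class_hit is not None:
        e_best = max(hom_e, EVALUE_FLOOR)
        e_other = max(homology_best_other_class_hit.evalue, EVALUE_FLOOR)
        if math.log10(e_other) - math.log10(e_best) >= config.group2_order_gap:
            return ClassPrediction(score_vector.sequence_id, hom_class, "II",
                                   hom_class, hom_e, score_vector)
    # Group III: total NB likelihood ratio vs runner-up class
    runner = score_vector.runner_up_class
    if runner is not None:
        delta = score_vector.total(comp_best) - score_vector.total(runner)
        if delta >= math.log(config.group3_ratio):
            return ClassPrediction(score_vector.sequence_id, comp_best, "III",
                                   hom_class, hom_e, score_vector)
    # Group IV: best NB likelihood only
    return ClassPrediction(score_vector.sequence_id, comp_best, "IV",
                           hom_class, hom_e, score_vector)


def best_hits_by_class(hits: Sequence[AlignmentHit]
                       ) -> tuple[Optional[AlignmentHit], Optional[AlignmentHit]]:
    """Split class-labelled hits into (best overall, best from any other
    class than the best hit's). Ties on e-value break by bitscore then id."""
    labelled = [h for h in hits if h.subject_class is not None]
    if not labelled:
        return None, None
    best = min(labelled, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    others = [h for h in labelled if h.subject_class != best.subject_class]
    if not others:
        return best, None
    other = min(others, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return best, other


def write_predictions_tsv(preds: Sequence[ClassPrediction],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tclass\tgroup\tbest_score\trunner_up_score\n")
        for p in preds:
            sv = p.composition_scores
            best = sv.scores[sv.best_class] if sv else float("nan")
            ru = sv.runner_up_class if sv else None
            ru_s = sv.scores[ru] if sv and ru else float("nan")
            fh.write(f"{p.sequence_id}\t{p.predicted_class}\t"
                     f"{p.confidence_group}\t{best:.6f}\t{ru_s:.6f}\n")
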