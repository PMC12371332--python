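"""Benchmark evaluation: pocket matching and extraction-quality metrics.

Extracted pockets are matched one-to-one against annotated pockets by
greedy assignment in decreasing order of annotated-residue recall
``|A ∩ E| / |A|``; a pair counts as a match when that overlap reaches the
match threshold (default 0.5). Extracted pockets left unpaired are *misses*
— fake pockets with no annotated counterpart.

From per-paper match results the suite reports:

- **Pocket Number Accuracy** — fraction of papers where the extracted pocket
  count equals the annotated count;
- **Pocket Recall** — matched annotated pockets over all annotated pockets
  (pooled across papers by default);
- **Pocket Specificity** (true negative rate) — ``1 − Σ misses / Σ extracted``;
- residue-level precision / recall / F1, macro-averaged over matched pairs.

The relevance-filter stage is additionally scored as a plain binary
classifier (accuracy, precision, recall, FPR, FNR) against the per-paper
``relevant`` flags.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "MetricsReport",
    "RelevanceMetrics",
    "match_pockets",
    "pocket_metrics",
    "residue_prf",
    "relevance_metrics",
    "max_matching_size",
]

ResidueKey = tuple[str, int, str]


def _key_set(pocket) -> frozenset[ResidueKey]:
    """Canonical residue-key set for a pocket-like object or a raw set."""
    if isinstance(pocket, (set, frozenset)):
        return frozenset(
            k.key if hasattr(k, "key") else tuple(k) for k in pocket
        )
    if hasattr(pocket, "residue_keys"):
        return pocket.residue_keys
    if hasattr(pocket, "residues"):
        return frozenset(r.key for r in pocket.residues)
    raise TypeError(f"cannot derive residue set from {type(pocket).__name__}")


@dataclass(frozen=True)
class MatchedPair:
    annotated_index: int
    extracted_index: int
    overlap: float          # |A ∩ E| / |A|
    precision: float        # residue-level, |A ∩ E| / |E|
    recall: float           # residue-level, |A ∩ E| / |A|
    f1: float


@dataclass
class MatchResult:
    """Outcome of matching one paper's extracted pockets to its annotations."""

    pairs: list[MatchedPair]
    n_annotated: int
    n_extracted: int

    def __post_init__(self) -> None:
        if self.n_matched_annotated > self.n_annotated:
            raise ValueError("more matches than annotated pockets")
        if self.n_misses > self.n_extracted:
            raise ValueError("more misses than extracted pockets")

    @property
    def n_matched_annotated(self) -> int:
        return len(self.pairs)

    @property
    def n_misses(self) -> int:
        """Extracted pockets with no annotated counterpart (fake pockets)."""
        return self.n_extracted - len(self.pairs)


def residue_prf(
    annotated_residues: Iterable | frozenset,
    extracted_residues: Iterable | frozenset,
) -> tuple[float, float, float]:
    """Residue-level precision, recall and F1 between two residue sets.

    Degenerate denominators are defined explicitly: an empty extracted set
    has precision 0, an empty annotated set has recall 0, and F1 is 0 when
    precision + recall is 0.
    """
    ann = _key_set(frozenset(annotated_residues))
    ext = _key_set(frozenset(extracted_residues))
    inter = len(ann & ext)
    if not ext:
        logger.info("residue_prf: empty extracted set, precision defined as 0")
    precision = inter / len(ext) if ext else 0.0
    recall = inter / len(ann) if ann else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def match_pockets(
    annotated: Sequence,
    extracted: Sequence,
    match_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of extracted to annotated pockets.

    Candidate pairs are ranked by decreasing annotated-residue recall
    ``|A ∩ E| / |A|``, ties broken by (annotated index, extracted index); a
    pair is accepted iff its overlap is positive and ≥ ``match_threshold``.
    Unpaired extracted pockets become misses.
    """
    ann_sets = [_key_set(p) for p in annotated]
    ext_sets = [_key_set(p) for p in extracted]
    candidates = []
    for ai, a in enumerate(ann_sets):
        for ei, e in enumerate(ext_sets):
            overlap = len(a & e) / len(a) if a else 0.0
            if overlap > 0.0 and overlap >= match_threshold:
                candidates.append((-overlap, ai, ei))
    candidates.sort()
    used_a: set[int] = set()
    used_e: set[int] = set()
    pairs: list[MatchedPair] = []
    for neg_overlap, ai, ei in candidates:
        if ai in used_a or ei in used_e:
            continue
        used_a.add(ai)
        used_e.add(ei)
        p, r, f1 = residue_prf(ann_sets[ai], ext_sets[ei])
        pairs.append(MatchedPair(ai, ei, -neg_overlap, p, r, f1))
    pairs.sort(key=lambda pr: (pr.annotated_index, pr.extracted_index))
    return MatchResult(pairs=pairs, n_annotated=len(ann_sets), n_extracted=len(ext_sets))


def max_matching_size(
    annotated: Sequence,
    extracted: Sequence,
    match_threshold: float = 0.5,
) -> int:
    """Exhaustive maximum-cardinality matching size under the same
    acceptance rule as :func:`match_pockets`.

    Brute force over injections — an independent oracle for small inputs
    (≤ ~6 pockets per side), not a production code path.
    """
    ann_sets = [_key_set(p) for p in annotated]
    ext_sets = [_key_set(p) for p in extracted]
    ok = [
        [
            bool(a) and (len(a & e) / len(a)) > 0.0 and (len(a & e) / len(a)) >= match_threshold
            for e in ext_sets
        ]
        for a in ann_sets
    ]
    best = 0
    n_a, n_e = len(ann_sets), len(ext_sets)
    for k in range(min(n_a, n_e), best, -1):
        for a_idx in itertools.combinations(range(n_a), k):
            for e_idx in itertools.permutations(range(n_e), k):
                if all(ok[ai][ei] for ai, ei in zip(a_idx, e_idx)):
                    return k
    return 0


@dataclass(frozen=True)
class MetricsReport:
    pocket_number_accuracy: float
    pocket_recall: float
    pocket_specificity: float
    residue_precision: float
    residue_recall: float
    residue_f1: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {value}")

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def pocket_metrics(results: Sequence[MatchResult], recall_averaging: str = "pooled") -> MetricsReport:
    """Aggregate per-paper match results into the evaluation report.

    ``recall_averaging``: ``"pooled"`` (default) divides total matched
    annotated pockets by total annotated pockets across papers; ``"macro"``
    averages the per-paper ratios (papers with no annotations excluded).
    Degenerate totals are defined explicitly: with no extracted pockets at
    all, specificity is 1.0 (no fake pocket was produced); with no annotated
    pockets, recall is 1.0.
    """
    if not results:
        raise ValueError("pocket_metrics needs at least one paper")
    if recall_averaging not in ("pooled", "macro"):
        raise ValueError(f"unknown recall_averaging {recall_averaging!r}")

    accuracy = sum(r.n_annotated == r.n_extracted for r in results) / len(results)

    total_ann = sum(r.n_annotated for r in results)
    total_matched = sum(r.n_matched_annotated for r in results)
    if recall_averaging == "pooled":
        if total_ann == 0:
            logger.info("no annotated pockets in any paper: recall defined as 1.0")
            recall = 1.0
        else:
            recall = total_matched / total_ann
    else:
        per_paper = [r.n_matched_annotated / r.n_annotated for r in results if r.n_annotated]
        recall = sum(per_paper) / len(per_paper) if per_paper else 1.0

    total_ext = sum(r.n_extracted for r in results)
    total_misses = sum(r.n_misses for r in results)
    if total_ext == 0:
        logger.info("no extracted pockets in any paper: specificity defined as 1.0")
        specificity = 1.0
    else:
        specificity = 1.0 - total_misses / total_ext

    pair_stats = [(p.precision, p.recall, p.f1) for r in results for p in r.pairs]
    if pair_stats:
        res_p = sum(s[0] for s in pair_stats) / len(pair_stats)
        res_r = sum(s[1] for s in pair_stats) / len(pair_stats)
        res_f = sum(s[2] for s in pair_stats) / len(pair_stats)
    else:
        logger.info("no matched pairs: residue-level metrics defined as 0.0")
        res_p = res_r = res_f = 0.0

    return MetricsReport(
        pocket_number_accuracy=accuracy,
        pocket_recall=recall,
        pocket_specificity=specificity,
        residue_precision=res_p,
        residue_recall=res_r,
        residue_f1=res_f,
    )


@dataclass(frozen=True)
class RelevanceMetrics:
    accuracy: float
    precision: float
    recall: float
    fpr: float
    fnr: float
    confusion: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))  # TP, FP, TN, FN

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "fpr": self.fpr,
            "fnr": self.fnr,
        }


def relevance_metrics(
    decisions: Sequence[tuple[str, bool]],
    truth: Sequence[tuple[str, bool]],
) -> RelevanceMetrics:
    """Binary-classification metrics for the relevance filter.

    ``decisions`` and ``truth`` are ``(doc_id, flag)`` sequences aligned by
    doc_id; pass ``(doc_id, decision.relevant)`` / ``(doc_id,
    annotation.relevant)`` pairs. A doc_id mismatch between the two sides is
    an error. Degenerate denominators: precision is 1.0 when nothing was
    predicted relevant, FPR is 0.0 when there are no irrelevant papers.
    """
    pred = {d: f for d, f in decisions}
    true = {d: f for d, f in truth}
    if set(pred) != set(true):
        raise ValueError(
            f"doc_id mismatch: only-in-decisions={sorted(set(pred) - set(true))}, "
            f"only-in-truth={sorted(set(true) - set(pred))}"
        )
    tp = sum(pred[d] and true[d] for d in pred)
    fp = sum(pred[d] and not true[d] for d in pred)
    tn = sum(not pred[d] and not true[d] for d in pred)
    fn = sum(not pred[d] and true[d] for d in pred)
    n = tp + fp + tn + fn
    accuracy = (tp + tn) / n if n else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return RelevanceMetrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        fpr=fpr,
        fnr=1.0 - recall,
        confusion=(tp, fp, tn, fn),
    )
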