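"""Exact/relaxed span matching, micro-averaged metrics, and error taxonomy.

Matching is one-to-one per document. Exact pairs are assigned first; in
relaxed mode the assignment is then extended to a maximum-cardinality
matching on the overlap-and-same-type graph via augmenting paths, which
guarantees exact-mode scores never exceed relaxed-mode scores and that the
assignment cardinality equals the bipartite-matching optimum.

Stop words are removed from both gold and predicted surfaces before they are
compared, so boundary disagreements confined to stop-word tokens do not
count as errors.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Literal, Mapping, Sequence

from .corpus import (
    ENTITY_TYPES,
    AnnotationSet,
    Document,
    EntityMention,
    overlap_chars,
    round_half_up,
    tokenize,
)
from .extraction import STOPWORDS, strip_stopwords

__all__ = [
    "ERROR_CATEGORIES",
    "MatchReport",
    "Metrics",
    "ErrorRecord",
    "ErrorTable",
    "is_exact_match",
    "is_relaxed_match",
    "assign_matches",
    "compute_metrics",
    "evaluate_corpus",
    "classify_errors",
    "error_table",
]

MatchMode = Literal["exact", "relaxed"]

ERROR_CATEGORIES: tuple[str, ...] = (
    "boundary_only",
    "type_only",
    "boundary_and_type",
    "spurious",
    "missed",
)


def _trimmed_span(doc: Document, mention: EntityMention) -> tuple[int, int]:
    """Mention span snapped to token edges, with edge stop-word tokens removed.

    Falls back to the full token range when every token is a stop word.
    """
    start, end = mention.fragments[0]
    tokens = tokenize(doc.text[start:end])
    kept = [t for t in tokens if t.surface.lower() not in STOPWORDS]
    if not kept:
        kept = tokens
    if not kept:  # surface with no tokens at all (e.g. pure whitespace slice)
        return start, end
    return start + kept[0].start, start + kept[-1].end


def _boundaries_match(doc: Document, a: EntityMention, b: EntityMention) -> bool:
    if not (a.grounded and b.grounded):
        return False
    if a.discontinuous or b.discontinuous:
        return a.fragments == b.fragments
    return (
        _trimmed_span(doc, a) == _trimmed_span(doc, b)
        and strip_stopwords(a.surface) == strip_stopwords(b.surface)
    )


def is_exact_match(gold: EntityMention, pred: EntityMention, doc: Document) -> bool:
    """Same entity type and same stop-word-trimmed boundaries."""
    return gold.entity_type == pred.entity_type and _boundaries_match(doc, gold, pred)


def is_relaxed_match(gold: EntityMention, pred: EntityMention) -> bool:
    """Same entity type and non-empty character overlap."""
    return gold.entity_type == pred.entity_type and overlap_chars(gold, pred) > 0


@dataclass
class MatchReport:
    """One-to-one assignment between a gold and a predicted set."""

    doc_id: str
    mode: MatchMode
    pairs: list[tuple[int, int, bool]]  # (gold index, pred index, exact flag)
    unmatched_gold: list[int]
    unmatched_pred: list[int]

    @property
    def n_correct(self) -> int:
        return len(self.pairs)


def _exact_stage(
    doc: Document, gold: Sequence[EntityMention], pred: Sequence[EntityMention]
) -> dict[int, int]:
    """Greedy exact pairing; optimal because exact match is a key equality."""
    match_g: dict[int, int] = {}
    used_p: set[int] = set()
    for gi, g in enumerate(gold):
        for pi, p in enumerate(pred):
            if pi in used_p:
                continue
            if is_exact_match(g, p, doc):
                match_g[gi] = pi
                used_p.add(pi)
                break
    return match_g


def _augment_to_maximum(
    gold: Sequence[EntityMention],
    pred: Sequence[EntityMention],
    match_g: dict[int, int],
) -> dict[int, int]:
    """Kuhn augmenting-path completion over the relaxed-eligibility graph."""
    edges: dict[int, list[int]] = {}
    for gi, g in enumerate(gold):
        cands = [pi for pi, p in enumerate(pred) if is_relaxed_match(g, p)]
        cands.sort(key=lambda pi: (-overlap_chars(g, pred[pi]), pi))
        edges[gi] = cands
    match_p = {pi: gi for gi, pi in match_g.items()}

    def try_augment(gi: int, visited: set[int]) -> bool:
        for pi in edges[gi]:
            if pi in visited:
                continue
            visited.add(pi)
            if pi not in match_p or try_augment(match_p[pi], visited):
                match_p[pi] = gi
                match_g[gi] = pi
                return True
        return False

    for gi in range(len(gold)):
        if gi not in match_g:
            try_augment(gi, set())
    return match_g


def assign_matches(
    doc: Document, gold: AnnotationSet, pred: AnnotationSet, mode: MatchMode
) -> MatchReport:
    """Assign predictions to gold mentions one-to-one under the given mode."""
    if gold.doc_id != pred.doc_id:
        raise ValueError(f"document mismatch: gold {gold.doc_id!r} vs pred {pred.doc_id!r}")
    if mode not in ("exact", "relaxed"):
        raise ValueError(f"invalid mode {mode!r}")
    g_mentions, p_mentions = gold.mentions, pred.mentions
    match_g = _exact_stage(doc, g_mentions, p_mentions)
    if mode == "relaxed":
        match_g = _augment_to_maximum(g_mentions, p_mentions, match_g)
    pairs = [
        (gi, pi, is_exact_match(g_mentions[gi], p_mentions[pi], doc))
        for gi, pi in sorted(match_g.items())
    ]
    matched_p = {pi for _, pi, _ in pairs}
    return MatchReport(
        doc_id=gold.doc_id,
        mode=mode,
        pairs=pairs,
        unmatched_gold=[gi for gi in range(len(g_mentions)) if gi not in match_g],
        unmatched_pred=[pi for pi in range(len(p_mentions)) if pi not in matched_p],
    )


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    n_correct: int
    m: int
    m_hat: int

    @classmethod
    def from_counts(cls, n_correct: int, m: int, m_hat: int) -> "Metrics":
        precision = n_correct / m_hat if m_hat else 0.0
        recall = n_correct / m if m else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        return cls(precision, recall, f1, n_correct, m, m_hat)

    def rounded(self, ndigits: int = 3) -> dict[str, float | int]:
        return {
            "precision": round_half_up(self.precision, ndigits),
            "recall": round_half_up(self.recall, ndigits),
            "f1": round_half_up(self.f1, ndigits),
            "n_correct": self.n_correct,
            "m": self.m,
            "m_hat": self.m_hat,
        }


def compute_metrics(reports: Iterable[MatchReport]) -> Metrics:
    """Micro-aggregate match reports: pool counts across documents, then divide."""
    n_correct = m = m_hat = 0
    seen: set[str] = set()
    for r in reports:
        if r.doc_id in seen:
            raise ValueError(f"duplicate report for document {r.doc_id!r}")
        seen.add(r.doc_id)
        n_correct += r.n_correct
        m += r.n_correct + len(r.unmatched_gold)
        m_hat += r.n_correct + len(r.unmatched_pred)
    return Metrics.from_counts(n_correct, m, m_hat)


def _restrict(ann: AnnotationSet, etype: str) -> AnnotationSet:
    return AnnotationSet(doc_id=ann.doc_id, role=ann.role, mentions=ann.of_type(etype))


def evaluate_corpus(
    documents: Mapping[str, Document],
    gold: Mapping[str, AnnotationSet],
    pred: Mapping[str, AnnotationSet],
    mode: MatchMode,
) -> dict[str, Metrics]:
    """Per-type and overall micro-averaged metrics over a document collection.

    Per-type scores restrict both sets to that type before matching; the
    ``overall`` row pools all four types. Documents missing from ``pred``
    contribute an empty prediction set.
    """
    results: dict[str, Metrics] = {}
    empty = lambda d: AnnotationSet(doc_id=d, role="predicted")  # noqa: E731
    for etype in ENTITY_TYPES:
        reports = [
            assign_matches(
                documents[d], _restrict(gold[d], etype), _restrict(pred.get(d, empty(d)), etype), mode
            )
            for d in sorted(gold)
        ]
        results[etype] = compute_metrics(reports)
    reports = [
        assign_matches(documents[d], gold[d], pred.get(d, empty(d)), mode) for d in sorted(gold)
    ]
    results["overall"] = compute_metrics(reports)
    return results


@dataclass(frozen=True)
class ErrorRecord:
    category: str
    entity_type: str
    gold_index: int | None = None
    pred_index: int | None = None

    def __post_init__(self) -> None:
        if self.category not in ERROR_CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")
        if self.category == "spurious" and self.gold_index is not None:
            raise ValueError("spurious records have no gold index")
        if self.category == "missed" and self.pred_index is not None:
            raise ValueError("missed records have no predicted index")


def classify_errors(
    doc: Document, gold: AnnotationSet, pred: AnnotationSet
) -> list[ErrorRecord]:
    """Classify every disagreement into the five-category error taxonomy.

    Exact matches produce no record. Remaining predictions are associated
    one-to-one with remaining gold mentions by decreasing character overlap;
    an associated pair is a boundary error, a type error, or both. Leftover
    predictions are spurious (false positives) and leftover gold mentions are
    missed (false negatives). Records where a gold mention participates are
    attributed to the gold mention's type; spurious records take the
    predicted type.
    """
    if gold.doc_id != pred.doc_id:
        raise ValueError(f"document mismatch: gold {gold.doc_id!r} vs pred {pred.doc_id!r}")
    g_mentions, p_mentions = gold.mentions, pred.mentions
    exact = _exact_stage(doc, g_mentions, p_mentions)
    rem_g = [gi for gi in range(len(g_mentions)) if gi not in exact]
    rem_p = [pi for pi in range(len(p_mentions)) if pi not in set(exact.values())]

    candidates = []
    for gi in rem_g:
        for pi in rem_p:
            ov = overlap_chars(g_mentions[gi], p_mentions[pi])
            if ov > 0:
                candidates.append((-ov, g_mentions[gi].start, pi, gi))
    candidates.sort()

    records: list[ErrorRecord] = []
    used_g: set[int] = set()
    used_p: set[int] = set()
    for _neg_ov, _gstart, pi, gi in candidates:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        g, p = g_mentions[gi], p_mentions[pi]
        same_type = g.entity_type == p.entity_type
        same_boundary = _boundaries_match(doc, g, p)
        if same_boundary and not same_type:
            category = "type_only"
        elif same_type:
            category = "boundary_only"
        else:
            category = "boundary_and_type"
        records.append(ErrorRecord(category, g.entity_type, gold_index=gi, pred_index=pi))
    for pi in rem_p:
        if pi not in used_p:
            records.append(
                ErrorRecord("spurious", p_mentions[pi].entity_type, pred_index=pi)
            )
    for gi in rem_g:
        if gi not in used_g:
            records.append(ErrorRecord("missed", g_mentions[gi].entity_type, gold_index=gi))
    return records


@dataclass
class ErrorTable:
    """Per-type counts for the five error categories, with integer percentages."""

    counts: dict[str, dict[str, int]]

    def total(self, entity_type: str) -> int:
        return sum(self.counts[entity_type].values())

    def percentage(self, entity_type: str, category: str) -> int:
        total = self.total(entity_type)
        if total == 0:
            return 0
        value = Decimal(self.counts[entity_type][category]) * 100 / Decimal(total)
        return int(value.quantize(Decimal("1"), rounding=ROUND_HALF_UP))

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for etype in ENTITY_TYPES:
            row: dict[str, object] = {"entity": etype}
            for cat in ERROR_CATEGORIES:
                row[cat] = self.counts[etype][cat]
                row[f"{cat}_pct"] = self.percentage(etype, cat)
            row["total"] = self.total(etype)
            rows.append(row)
        return rows

    def to_csv(self) -> str:
        buf = io.StringIO()
        rows = self.to_rows()
        writer = csv.DictWriter(buf, fieldnames=list(rows[0].keys()), lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
        return buf.getvalue()


def error_table(records: Iterable[ErrorRecord]) -> ErrorTable:
    counts = {t: {c: 0 for c in ERROR_CATEGORIES} for t in ENTITY_TYPES}
    for r in records:
        counts[r.entity_type][r.category] += 1
    return ErrorTable(counts=counts)
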