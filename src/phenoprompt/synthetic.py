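"""Synthetic corpora with known gold annotations and controlled corruption.

The generator emulates the profile of the motivating corpus: multi-sentence
disease descriptions, per-document entity counts drawn from per-type Poisson
means, all four entity types, and occasional repeated surface forms. Gold
offsets are recorded at fill time, never re-searched.

The injector is the constructive inverse of the error taxonomy: it corrupts
gold annotations into predictions containing an exactly specified number of
boundary, type, boundary-and-type, spurious, and missed errors, so the
classifier can be tested by parameter recovery.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import (
    ENTITY_TYPES,
    AnnotationSet,
    Document,
    EntityMention,
    overlap_chars,
    save_corpus,
    tokenize,
)
from .evaluation import _boundaries_match, is_exact_match, is_relaxed_match
from .extraction import parse_envelope
from .prompts import render_entity_lines

__all__ = [
    "GeneratorConfig",
    "ErrorInjectionConfig",
    "generate_corpus",
    "inject_errors",
    "GoldEchoProvider",
    "gold_echo_provider",
    "DEFAULT_VOCAB",
    "DEFAULT_TEMPLATES",
]

#: Per-type surface vocabularies. Disjoint across types, and no surface is a
#: substring of another surface or of any template text, so grounding by
#: substring search is unambiguous.
DEFAULT_VOCAB: dict[str, list[str]] = {
    "rare_disease": [
        "keratomalacia",
        "morquio syndrome",
        "alkaptonuria",
        "cystinosis",
        "netherton syndrome",
        "leigh syndrome",
        "fibrodysplasia ossificans",
        "achalasia cardia",
    ],
    "disease": [
        "glaucoma",
        "nephritis",
        "osteoarthritis",
        "pericarditis",
        "bronchiectasis",
        "hepatitis",
    ],
    "symptom": [
        "nausea",
        "dizziness",
        "malaise",
        "drowsiness",
        "photophobia",
        "restlessness",
    ],
    "sign": [
        "papilledema",
        "splenomegaly",
        "bradycardia",
        "hypotonia",
        "jaundice",
        "corneal scarring",
    ],
}

#: Sentence templates, one ``{e}`` placeholder each.
DEFAULT_TEMPLATES: dict[str, list[str]] = {
    "rare_disease": [
        "{e} is a rare inherited disorder that affects only a small number of people worldwide.",
        "Researchers first described {e} in a series of case reports.",
        "{e} belongs to a group of uncommon metabolic disorders.",
    ],
    "disease": [
        "Affected individuals may later develop {e} as the condition progresses.",
        "{e} is a recognized medical condition with an identifiable cause.",
    ],
    "symptom": [
        "Patients often complain of {e} during the early stages.",
        "Subjective complaints such as {e} are also frequent.",
    ],
    "sign": [
        "Physical examination may reveal {e} in affected individuals.",
        "Laboratory and imaging studies frequently demonstrate {e}.",
    ],
}

#: Every generated document opens with this entity-free sentence; its terms
#: provide guaranteed non-gold spans for spurious-error injection.
OPENING_SENTENCE = "The prognosis and overall outlook of this condition remain under active study."
DISTRACTOR_TERMS = ("prognosis", "overall outlook", "active study")


@dataclass(frozen=True)
class GeneratorConfig:
    n_docs: int = 200
    means: Mapping[str, float] = field(
        default_factory=lambda: {"rare_disease": 4.9, "disease": 2.2, "symptom": 0.4, "sign": 4.0}
    )
    vocab: Mapping[str, Sequence[str]] = field(default_factory=lambda: dict(DEFAULT_VOCAB))
    templates: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs <= 0:
            raise ValueError("n_docs must be positive")
        for etype, mean in self.means.items():
            if etype not in ENTITY_TYPES:
                raise ValueError(f"unknown entity type {etype!r}")
            if mean > 0 and not self.vocab.get(etype):
                raise ValueError(f"empty vocabulary for type {etype!r} with positive mean")
            if mean > 0 and not self.templates.get(etype):
                raise ValueError(f"no templates for type {etype!r} with positive mean")


def _poisson(rng: random.Random, mean: float) -> int:
    """Knuth's Poisson sampler; fine for the small means used here."""
    if mean <= 0:
        return 0
    import math

    limit = math.exp(-mean)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def generate_corpus(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> list[tuple[Document, AnnotationSet]]:
    """Generate ``n_docs`` documents with gold annotations recorded at fill time.

    Deterministic given ``config.seed``; with ``out_dir`` the corpus is also
    persisted as ``.txt``/``.ann`` pairs (byte-identical across runs).
    """
    rng = random.Random(config.seed)
    corpus: list[tuple[Document, AnnotationSet]] = []
    for i in range(config.n_docs):
        doc_id = f"doc{i:04d}"
        slots: list[tuple[str, str, str]] = []  # (template, surface, type)
        for etype in ENTITY_TYPES:
            count = _poisson(rng, float(config.means.get(etype, 0.0)))
            for _ in range(count):
                template = config.templates[etype][rng.randrange(len(config.templates[etype]))]
                surface = config.vocab[etype][rng.randrange(len(config.vocab[etype]))]
                slots.append((template, surface, etype))
        rng.shuffle(slots)
        parts = [OPENING_SENTENCE]
        offset = len(OPENING_SENTENCE)
        mentions: list[EntityMention] = []
        for template, surface, etype in slots:
            prefix, _, suffix = template.partition("{e}")
            sentence = prefix + surface + suffix
            start = offset + 1 + len(prefix)  # +1 for the joining space
            mentions.append(
                EntityMention(((start, start + len(surface)),), etype, surface)
            )
            parts.append(sentence)
            offset += 1 + len(sentence)
        doc = Document(doc_id=doc_id, text=" ".join(parts), source="synthetic")
        ann = AnnotationSet(doc_id=doc_id, role="gold", mentions=mentions)
        ann.validate_against(doc)
        corpus.append((doc, ann))
    if out_dir is not None:
        save_corpus(out_dir, corpus)
    return corpus


@dataclass(frozen=True)
class ErrorInjectionConfig:
    boundary_only: int = 0
    type_only: int = 0
    boundary_and_type: int = 0
    spurious: int = 0
    missed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("boundary_only", "type_only", "boundary_and_type", "spurious", "missed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")

    def total(self) -> int:
        return self.boundary_only + self.type_only + self.boundary_and_type + self.spurious + self.missed


def _mention_dict(m: EntityMention) -> dict:
    return {
        "fragments": [list(f) for f in m.fragments],
        "entity_type": m.entity_type,
        "surface": m.surface,
    }


def _boundary_candidates(doc: Document, m: EntityMention) -> Iterable[tuple[int, int]]:
    """Whole-token span edits of a continuous mention: shrinks, then extensions."""
    s, e = m.fragments[0]
    inner = tokenize(doc.text[s:e])
    if len(inner) >= 2:
        yield (s, s + inner[-2].end)  # drop last token
        yield (s + inner[1].start, e)  # drop first token
    all_tokens = tokenize(doc.text)
    right = [t for t in all_tokens if t.start >= e]
    left = [t for t in all_tokens if t.end <= s]
    for k in range(1, min(4, len(right)) + 1):
        yield (s, right[k - 1].end)
    for k in range(1, min(4, len(left)) + 1):
        yield (left[-k].start, e)


def _other_type(rng: random.Random, etype: str) -> str:
    return rng.choice([t for t in ENTITY_TYPES if t != etype])


def inject_errors(
    corpus: Sequence[tuple[Document, AnnotationSet]],
    config: ErrorInjectionConfig,
) -> tuple[dict[str, AnnotationSet], list[dict]]:
    """Corrupt gold annotations into predictions with exact per-category counts.

    Returns the predicted annotation sets and a ledger with one entry per
    injected error. ``classify_errors`` on the result recovers exactly the
    configured counts (the injector validates each corruption against the
    matching predicates before accepting it).

    Raises ``ValueError`` with the shortfall when a category cannot be filled.
    """
    rng = random.Random(config.seed)
    docs = {doc.doc_id: doc for doc, _ in corpus}
    gold = {ann.doc_id: ann for _, ann in corpus}
    # predictions start as verbatim copies of gold
    pred_mentions: dict[str, list[EntityMention]] = {
        doc_id: list(ann.mentions) for doc_id, ann in gold.items()
    }

    pool = [
        (doc_id, idx)
        for doc_id in sorted(gold)
        for idx in range(len(gold[doc_id].mentions))
    ]
    consuming = config.boundary_only + config.type_only + config.boundary_and_type + config.missed
    if consuming > len(pool):
        raise ValueError(
            f"cannot inject {consuming} mention-consuming errors: only "
            f"{len(pool)} gold mentions available (shortfall {consuming - len(pool)})"
        )
    rng.shuffle(pool)
    ledger: list[dict] = []

    def take_valid(category: str) -> None:
        """Pop pool entries until one admits a valid corruption of `category`."""
        tried: list[tuple[str, int]] = []
        while pool:
            doc_id, idx = pool.pop()
            doc, m = docs[doc_id], gold[doc_id].mentions[idx]
            corrupted = _corrupt(doc, doc_id, m, category)
            if corrupted is not None or category == "missed":
                pos = pred_mentions[doc_id].index(m)
                if category == "missed":
                    del pred_mentions[doc_id][pos]
                else:
                    pred_mentions[doc_id][pos] = corrupted  # type: ignore[assignment]
                ledger.append(
                    {
                        "doc_id": doc_id,
                        "category": category,
                        "original": _mention_dict(m),
                        "corrupted": _mention_dict(corrupted) if corrupted else None,
                    }
                )
                pool.extend(tried)
                return
            tried.append((doc_id, idx))
        raise ValueError(f"no feasible corruption target left for category {category!r}")

    def _corrupt(doc: Document, doc_id: str, m: EntityMention, category: str):
        if category == "missed":
            return None
        others = [g for g in gold[doc_id].mentions if g is not m]
        if category == "type_only":
            cand = EntityMention(m.fragments, _other_type(rng, m.entity_type), m.surface)
            return cand
        if m.discontinuous:
            return None  # boundary edits operate on continuous mentions only
        for ns, ne in _boundary_candidates(doc, m):
            new_type = m.entity_type if category == "boundary_only" else _other_type(rng, m.entity_type)
            cand = EntityMention.from_document(doc, [(ns, ne)], new_type)
            if any(overlap_chars(cand, g) > 0 for g in others):
                continue  # must stay unambiguous: overlap its own gold only
            if _boundaries_match(doc, m, cand):
                continue  # edit confined to stop-word tokens: not a boundary error
            if category == "boundary_only" and not (
                is_relaxed_match(m, cand) and not is_exact_match(m, cand, doc)
            ):
                continue
            if category == "boundary_and_type" and overlap_chars(m, cand) == 0:
                continue
            return cand
        return None

    for _ in range(config.missed):
        take_valid("missed")
    for _ in range(config.type_only):
        take_valid("type_only")
    for _ in range(config.boundary_only):
        take_valid("boundary_only")
    for _ in range(config.boundary_and_type):
        take_valid("boundary_and_type")

    # spurious insertions over distractor spans that overlap no gold mention
    slots: list[tuple[str, int, int]] = []
    for doc_id in sorted(gold):
        text_lower = docs[doc_id].text.lower()
        for term in DISTRACTOR_TERMS:
            start = 0
            while True:
                pos = text_lower.find(term, start)
                if pos < 0:
                    break
                span = EntityMention(((pos, pos + len(term)),), "sign", term)
                if not any(overlap_chars(span, g) > 0 for g in gold[doc_id].mentions):
                    slots.append((doc_id, pos, pos + len(term)))
                start = pos + len(term)
    if config.spurious > len(slots):
        raise ValueError(
            f"cannot inject {config.spurious} spurious errors: only {len(slots)} "
            f"distractor spans available (shortfall {config.spurious - len(slots)})"
        )
    rng.shuffle(slots)
    for _ in range(config.spurious):
        doc_id, s, e = slots.pop()
        cand = EntityMention.from_document(docs[doc_id], [(s, e)], rng.choice(ENTITY_TYPES))
        pred_mentions[doc_id].append(cand)
        ledger.append(
            {"doc_id": doc_id, "category": "spurious", "original": None, "corrupted": _mention_dict(cand)}
        )

    predictions = {
        doc_id: AnnotationSet(
            doc_id=doc_id,
            role="predicted",
            mentions=sorted(ms, key=lambda m: (m.start, m.end)),
        )
        for doc_id, ms in pred_mentions.items()
    }
    if len(ledger) != config.total():
        raise AssertionError("ledger length does not match configured counts")
    return predictions, ledger


def write_ledger(path: str | Path, ledger: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entry in ledger:
            fh.write(json.dumps(entry, ensure_ascii=False) + "\n")


class GoldEchoProvider:
    """Deterministic offline provider that echoes stored annotations.

    Looks up the target document from the prompt envelope and renders that
    document's annotation surfaces (document order, repeats kept) in the
    canonical labeled comma-separated output format. Unknown documents get an
    empty response.
    """

    def __init__(self, annotations: Mapping[str, AnnotationSet]):
        self.annotations = dict(annotations)

    def complete(self, prompt: str) -> str:
        doc_id, _ = parse_envelope(prompt)
        if doc_id is None or doc_id not in self.annotations:
            return ""
        ann = self.annotations[doc_id]
        lists: dict[str, list[str]] = {t: [] for t in ENTITY_TYPES}
        for m in sorted(
            ann.mentions, key=lambda m: (m.start, m.end) if m.grounded else (-1, -1)
        ):
            lists[m.entity_type].append(m.surface)
        return render_entity_lines(lists)


def gold_echo_provider(
    corpus: Sequence[tuple[Document, AnnotationSet]] | Mapping[str, AnnotationSet],
) -> GoldEchoProvider:
    """Build a :class:`GoldEchoProvider` from a corpus or an annotation map."""
    if isinstance(corpus, Mapping):
        return GoldEchoProvider(corpus)
    return GoldEchoProvider({ann.doc_id: ann for _, ann in corpus})
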