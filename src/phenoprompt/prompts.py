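"""Prompt assembly and few-shot example selection.

Prompts are assembled from five building blocks — task instruction, task
guidance (entity definitions, optionally with distinguishing
characteristics), output specification, a worked example (few-shot only),
and an output-retrieval cue — rendered either as conversational sentences
(``simple_sentence``) or as a numbered recipe (``structured_list``). All
block texts live in a versioned YAML resource so templates can evolve
without code changes.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Literal, Mapping, Sequence

import yaml

from .corpus import ENTITY_TYPES, AnnotationSet, Document, tokenize

__all__ = [
    "PromptSpec",
    "FewShotExample",
    "build_prompt",
    "render_entity_lines",
    "select_random_example",
    "select_similar_example",
    "default_similarity",
    "prompt_texts",
]

EMPTY_SENTINEL = "none"


def prompt_texts() -> dict:
    """Load the packaged prompt building-block texts."""
    raw = resources.files("phenoprompt.resources").joinpath("prompt_texts.yaml").read_text(
        encoding="utf-8"
    )
    return yaml.safe_load(raw)


_TEXTS = prompt_texts()
TYPE_DISPLAY: dict[str, str] = dict(_TEXTS["entity_display_names"])


@dataclass(frozen=True)
class PromptSpec:
    """Configuration of a prompt: setting, format, and block texts."""

    setting: Literal["zero_shot", "few_shot"] = "zero_shot"
    format: Literal["simple_sentence", "structured_list"] = "simple_sentence"
    include_characteristics: bool = False
    entity_definitions: Mapping[str, str] = field(
        default_factory=lambda: dict(_TEXTS["entity_definitions"])
    )
    characteristics: Mapping[str, str] = field(
        default_factory=lambda: dict(_TEXTS["characteristics"])
    )
    task_instruction: str = _TEXTS["task_instruction"]
    output_format_instruction: str = _TEXTS["output_specification"]
    example_header: str = _TEXTS["example_header"]
    output_retrieval: str = _TEXTS["output_retrieval"]

    def __post_init__(self) -> None:
        if self.setting not in ("zero_shot", "few_shot"):
            raise ValueError(f"invalid setting {self.setting!r}")
        if self.format not in ("simple_sentence", "structured_list"):
            raise ValueError(f"invalid format {self.format!r}")
        if set(self.entity_definitions) != set(ENTITY_TYPES):
            raise ValueError("entity_definitions must cover exactly the four entity types")
        if self.include_characteristics and not set(ENTITY_TYPES) <= set(self.characteristics):
            raise ValueError("include_characteristics requires texts for all four types")


@dataclass(frozen=True)
class FewShotExample:
    """A training text plus its gold surfaces, for embedding in a prompt."""

    example_text: str
    gold_lists: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        lowered = self.example_text.lower()
        for etype, surfaces in self.gold_lists.items():
            if etype not in ENTITY_TYPES:
                raise ValueError(f"invalid entity type {etype!r}")
            for s in surfaces:
                if s.lower() not in lowered:
                    raise ValueError(
                        f"gold surface {s!r} does not occur in the example text"
                    )

    @classmethod
    def from_annotations(cls, doc: Document, ann: AnnotationSet) -> "FewShotExample":
        """Gold surfaces in document order, deduplicated case-insensitively."""
        lists: dict[str, list[str]] = {t: [] for t in ENTITY_TYPES}
        seen: dict[str, set[str]] = {t: set() for t in ENTITY_TYPES}
        for m in sorted(ann.mentions, key=lambda m: (m.start, m.end) if m.grounded else (0, 0)):
            key = m.surface.lower()
            if key not in seen[m.entity_type]:
                seen[m.entity_type].add(key)
                lists[m.entity_type].append(m.surface)
        return cls(example_text=doc.text, gold_lists=lists)


def render_entity_lines(lists: Mapping[str, Sequence[str]]) -> str:
    """Render per-type surface lists in the canonical labeled comma-separated format."""
    lines = []
    for etype in ENTITY_TYPES:
        surfaces = list(lists.get(etype, []))
        body = ", ".join(surfaces) if surfaces else EMPTY_SENTINEL
        lines.append(f"{TYPE_DISPLAY[etype]}: {body}")
    return "\n".join(lines)


def _render_example(example: FewShotExample) -> str:
    return (
        f"Input text: {example.example_text}\n"
        f"Output:\n{render_entity_lines(example.gold_lists)}"
    )


def build_prompt(
    spec: PromptSpec, target_text: str, example: FewShotExample | None = None
) -> str:
    """Render a complete prompt for one target text.

    Pure function of its arguments: identical inputs yield identical strings.
    """
    if spec.setting == "few_shot" and example is None:
        raise ValueError("few_shot prompts require an example")
    if spec.setting == "zero_shot" and example is not None:
        raise ValueError("zero_shot prompts must not include an example")

    if spec.format == "simple_sentence":
        guidance_bits = []
        for etype in ENTITY_TYPES:
            bit = f"A {TYPE_DISPLAY[etype]} is defined as: {spec.entity_definitions[etype]}."
            if spec.include_characteristics:
                bit += f" {spec.characteristics[etype]}"
            guidance_bits.append(bit)
        parts = [
            f"{spec.task_instruction} {' '.join(guidance_bits)} "
            f"{spec.output_format_instruction}"
        ]
        if example is not None:
            parts.append(f"{spec.example_header}\n{_render_example(example)}")
        parts.append(f"Input text: {target_text}")
        parts.append(spec.output_retrieval)
        return "\n\n".join(parts)

    # structured_list
    sections: list[str] = []
    n = 1
    sections.append(f"{n}. Task: {spec.task_instruction}")
    n += 1
    defs = "\n".join(
        f"   - {TYPE_DISPLAY[t]}: {spec.entity_definitions[t]}" for t in ENTITY_TYPES
    )
    sections.append(f"{n}. Entity definitions:\n{defs}")
    n += 1
    if spec.include_characteristics:
        chars = "\n".join(
            f"   - {TYPE_DISPLAY[t]}: {spec.characteristics[t]}" for t in ENTITY_TYPES
        )
        sections.append(f"{n}. Distinguishing characteristics:\n{chars}")
        n += 1
    sections.append(f"{n}. Output format: {spec.output_format_instruction}")
    n += 1
    if example is not None:
        sections.append(f"{n}. Example:\n{_render_example(example)}")
        n += 1
    sections.append(f"{n}. Input text: {target_text}")
    n += 1
    sections.append(f"{n}. {spec.output_retrieval}")
    return "\n".join(sections)


def select_random_example(training_ids: Sequence[str], seed: int) -> str:
    """Uniform, seed-deterministic choice of one training document id."""
    if not training_ids:
        raise ValueError("training set is empty")
    rng = random.Random(seed)
    return training_ids[rng.randrange(len(training_ids))]


def default_similarity(a: str, b: str) -> float:
    """Cosine similarity between raw term-frequency bag-of-tokens vectors.

    Tokens are the lower-cased surfaces of :func:`phenoprompt.corpus.tokenize`.
    Returns 0.0 when either text contains no tokens.
    """
    ta = [t.surface.lower() for t in tokenize(a)]
    tb = [t.surface.lower() for t in tokenize(b)]
    if not ta or not tb:
        return 0.0
    ca: dict[str, int] = {}
    cb: dict[str, int] = {}
    for t in ta:
        ca[t] = ca.get(t, 0) + 1
    for t in tb:
        cb[t] = cb.get(t, 0) + 1
    dot = sum(ca[t] * cb.get(t, 0) for t in ca)
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return dot / (na * nb)


def select_similar_example(
    training_corpus: Mapping[str, str],
    target_text: str,
    scorer: Callable[[str, str], float] = default_similarity,
) -> str:
    """Return the training doc id maximizing ``scorer(target_text, candidate)``.

    Ties break to the lexicographically smallest doc id, so the result does
    not depend on corpus ordering.
    """
    if not training_corpus:
        raise ValueError("training corpus is empty")
    best_id: str | None = None
    best_score = -math.inf
    for doc_id in sorted(training_corpus):
        score = scorer(target_text, training_corpus[doc_id])
        if not math.isfinite(score):
            raise ValueError(f"similarity scorer returned {score!r} for candidate {doc_id!r}")
        if score > best_score:
            best_id, best_score = doc_id, score
    assert best_id is not None
    return best_id
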