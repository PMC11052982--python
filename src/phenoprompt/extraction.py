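"""Running prompts against a completion provider and grounding the output.

The provider is a contract: anything with ``complete(prompt) -> str``.
Shipped implementations are deterministic mocks (see
:mod:`phenoprompt.synthetic`) and a generic HTTP completion adapter that is
never exercised by the test suite. Responses in the labeled comma-separated
format are parsed totally (garbage accumulates in a remainder field) and
each extracted surface is grounded back to character offsets by
case-insensitive, leftmost-unconsumed substring search.
"""

from __future__ import annotations

import json
import re
import time
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol

from .corpus import ENTITY_TYPES, AnnotationSet, Document, EntityMention, tokenize
from .prompts import FewShotExample, PromptSpec, build_prompt, select_random_example, select_similar_example

__all__ = [
    "STOPWORDS",
    "ProviderConfig",
    "CompletionProvider",
    "RawExtraction",
    "ExtractionResult",
    "parse_response",
    "ground_mentions",
    "strip_stopwords",
    "run_extraction",
    "wrap_envelope",
    "parse_envelope",
    "HTTPCompletionProvider",
]


def _load_stopwords() -> frozenset[str]:
    raw = resources.files("phenoprompt.resources").joinpath("stopwords.txt").read_text(
        encoding="utf-8"
    )
    return frozenset(
        line.strip() for line in raw.splitlines() if line.strip() and not line.startswith("#")
    )


#: Packaged stop-word list applied to both gold and predicted surfaces.
STOPWORDS: frozenset[str] = _load_stopwords()


def strip_stopwords(surface: str) -> list[str]:
    """Lower-cased content tokens of a surface, stop words removed.

    If every token is a stop word the full lower-cased token list is returned
    unchanged, so no surface normalizes to the empty sequence.
    """
    tokens = [t.surface.lower() for t in tokenize(surface)]
    content = [t for t in tokens if t not in STOPWORDS]
    return content if content else tokens


@dataclass(frozen=True)
class ProviderConfig:
    model_name: str = "mock"
    temperature: float = 0.0
    max_retries: int = 2


class CompletionProvider(Protocol):
    def complete(self, prompt: str) -> str: ...


@dataclass
class RawExtraction:
    """Parsed per-type surface lists plus any unparseable remainder."""

    lists: dict[str, list[str]]
    unparsed_remainder: str = ""

    def n_items(self) -> int:
        return sum(len(v) for v in self.lists.values())


@dataclass
class ExtractionResult:
    """Grounded predictions for one document."""

    predictions: AnnotationSet
    ungrounded: list[tuple[str, str]] = field(default_factory=list)
    error: str | None = None


_SENTINELS = {"none", "n/a", "na", "-", ""}

# Longest alias first so "rare disease" wins over "disease".
_TYPE_LINE = re.compile(
    r"^[\s\-\*\d\.\)]*(?P<label>rare[ _\-]?diseases?|diseases?|symptoms?|signs?)\s*:\s*(?P<body>.*)$",
    re.IGNORECASE,
)


def _canonical_label(label: str) -> str:
    key = re.sub(r"[ _\-]", "", label.lower())
    if key.startswith("raredisease"):
        return "rare_disease"
    if key.startswith("disease"):
        return "disease"
    if key.startswith("symptom"):
        return "symptom"
    return "sign"


def parse_response(response: str) -> RawExtraction:
    """Total parser for the labeled comma-separated output format.

    Lines of the form ``<entity type>: a, b, c`` populate the per-type lists;
    items are trimmed of whitespace and enclosing quotes, and sentinel values
    (``none``, ``n/a``, empty) are dropped. Everything else lands in
    ``unparsed_remainder``.
    """
    lists: dict[str, list[str]] = {t: [] for t in ENTITY_TYPES}
    remainder: list[str] = []
    for line in response.splitlines():
        if not line.strip():
            continue
        m = _TYPE_LINE.match(line)
        if m is None:
            remainder.append(line)
            continue
        etype = _canonical_label(m.group("label"))
        for item in m.group("body").split(","):
            item = item.strip().strip("\"'“”‘’`").strip()
            if item.lower() in _SENTINELS:
                continue
            lists[etype].append(item)
    return RawExtraction(lists=lists, unparsed_remainder="\n".join(remainder))


def ground_mentions(doc: Document, raw: RawExtraction) -> ExtractionResult:
    """Locate each extracted surface in the document text.

    Search is case-insensitive, exact-substring, and leftmost-unconsumed per
    surface: repeated extractions of the same surface walk forward through
    its occurrences. Surfaces that cannot be located stay in the prediction
    set as ungrounded mentions (they still count toward m̂) and are also
    listed separately.
    """
    text_lower = doc.text.lower()
    next_offset: dict[str, int] = {}
    mentions: list[EntityMention] = []
    ungrounded: list[tuple[str, str]] = []
    for etype in ENTITY_TYPES:
        for surface in raw.lists[etype]:
            key = surface.lower()
            pos = text_lower.find(key, next_offset.get(key, 0))
            if pos >= 0:
                next_offset[key] = pos + len(key)
                mentions.append(
                    EntityMention.from_document(doc, [(pos, pos + len(key))], etype)
                )
            else:
                ungrounded.append((surface, etype))
                mentions.append(EntityMention.ungrounded(surface, etype))
    return ExtractionResult(
        predictions=AnnotationSet(doc_id=doc.doc_id, role="predicted", mentions=mentions),
        ungrounded=ungrounded,
    )


_ENVELOPE_RE = re.compile(r"^\[\[document:(?P<doc_id>[^\]]*)\]\]\n", re.DOTALL)


def wrap_envelope(doc_id: str, prompt: str) -> str:
    """Prefix a prompt with a machine-readable target-document identifier.

    The envelope lets offline mock providers look up the right response; the
    HTTP adapter strips it before transmission.
    """
    return f"[[document:{doc_id}]]\n{prompt}"


def parse_envelope(wrapped: str) -> tuple[str | None, str]:
    m = _ENVELOPE_RE.match(wrapped)
    if m is None:
        return None, wrapped
    return m.group("doc_id"), wrapped[m.end() :]


def _audit(fh, record: dict) -> None:
    if fh is not None:
        fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def run_extraction(
    documents: Mapping[str, Document],
    spec: PromptSpec,
    provider: CompletionProvider,
    *,
    provider_config: ProviderConfig | None = None,
    training: Mapping[str, tuple[Document, AnnotationSet]] | None = None,
    example_strategy: str = "random",
    seed: int = 0,
    audit_path: str | Path | None = None,
    sleep: Callable[[float], None] = time.sleep,
) -> dict[str, ExtractionResult]:
    """Build, send, parse, and ground a prompt for every document.

    Few-shot runs draw one example per document from ``training`` (which must
    be disjoint from the evaluated documents), either uniformly at random or
    by maximal text similarity. Every provider call is recorded in a
    JSON-lines audit log as a prompt record followed by a response record.
    Provider failures are retried with bounded exponential backoff; a
    document whose calls all fail stays in the result map with an ``error``.
    """
    cfg = provider_config or ProviderConfig()
    if spec.setting == "few_shot":
        if not training:
            raise ValueError("few_shot extraction requires a training corpus")
        overlap = set(documents) & set(training)
        if overlap:
            raise ValueError(f"evaluated documents appear in the training set: {sorted(overlap)}")

    fh = open(audit_path, "a", encoding="utf-8") if audit_path is not None else None
    rng_seq = list(enumerate(sorted(documents)))
    results: dict[str, ExtractionResult] = {}
    try:
        for i, doc_id in rng_seq:
            doc = documents[doc_id]
            example = None
            if spec.setting == "few_shot":
                assert training is not None
                if example_strategy == "random":
                    ex_id = select_random_example(sorted(training), seed + i)
                elif example_strategy == "similar":
                    ex_id = select_similar_example(
                        {k: v[0].text for k, v in training.items()}, doc.text
                    )
                else:
                    raise ValueError(f"unknown example strategy {example_strategy!r}")
                ex_doc, ex_ann = training[ex_id]
                example = FewShotExample.from_annotations(ex_doc, ex_ann)
            prompt = wrap_envelope(doc_id, build_prompt(spec, doc.text, example))
            _audit(
                fh,
                {
                    "doc_id": doc_id,
                    "kind": "prompt",
                    "body": prompt,
                    "model_name": cfg.model_name,
                    "timestamp": datetime.now(timezone.utc).isoformat(),
                },
            )
            response: str | None = None
            last_exc: Exception | None = None
            for attempt in range(cfg.max_retries + 1):
                try:
                    response = provider.complete(prompt)
                    break
                except Exception as exc:  # provider contract: anything can fail
                    last_exc = exc
                    if attempt < cfg.max_retries:
                        sleep(min(2.0**attempt * 0.1, 5.0))
            if response is None:
                _audit(
                    fh,
                    {
                        "doc_id": doc_id,
                        "kind": "response",
                        "body": "",
                        "error": str(last_exc),
                        "model_name": cfg.model_name,
                        "timestamp": datetime.now(timezone.utc).isoformat(),
                    },
                )
                results[doc_id] = ExtractionResult(
                    predictions=AnnotationSet(doc_id=doc_id, role="predicted"),
                    error=str(last_exc),
                )
                continue
            _audit(
                fh,
                {
                    "doc_id": doc_id,
                    "kind": "response",
                    "body": response,
                    "model_name": cfg.model_name,
                    "timestamp": datetime.now(timezone.utc).isoformat(),
                },
            )
            results[doc_id] = ground_mentions(doc, parse_response(response))
    finally:
        if fh is not None:
            fh.close()
    return results


class HTTPCompletionProvider:
    """Minimal adapter for an OpenAI-style chat-completions endpoint.

    Exists for real runs only; the test suite never constructs it with a live
    endpoint. Temperature is forced to the configured value (default 0).
    """

    def __init__(self, endpoint: str, api_key: str = "", config: ProviderConfig | None = None):
        self.endpoint = endpoint
        self.api_key = api_key
        self.config = config or ProviderConfig(model_name="gpt-3.5-turbo")

    def complete(self, prompt: str) -> str:
        _, body = parse_envelope(prompt)
        payload = json.dumps(
            {
                "model": self.config.model_name,
                "temperature": self.config.temperature,
                "messages": [{"role": "user", "content": body}],
            }
        ).encode("utf-8")
        req = urllib.request.Request(
            self.endpoint,
            data=payload,
            headers={
                "Content-Type": "application/json",
                **({"Authorization": f"Bearer {self.api_key}"} if self.api_key else {}),
            },
        )
        with urllib.request.urlopen(req, timeout=60) as resp:
            data = json.loads(resp.read().decode("utf-8"))
        return data["choices"][0]["message"]["content"]
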