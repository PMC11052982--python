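"""Documents, typed entity spans, brat standoff I/O, BIO codec, and corpus utilities.

Character offsets are 0-based and end-exclusive throughout (brat convention).
Discontinuous annotations (``;``-separated fragment lists) are parsed and
preserved; codecs that cannot represent them say so explicitly.
"""

from __future__ import annotations

import math
import random
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "ENTITY_TYPES",
    "Document",
    "EntityMention",
    "AnnotationSet",
    "Token",
    "BioSequence",
    "TypeStats",
    "CorpusStats",
    "BratParseError",
    "parse_brat",
    "write_brat",
    "tokenize",
    "to_bio",
    "from_bio",
    "corpus_stats",
    "split_corpus",
    "load_corpus",
    "save_corpus",
    "normalize_entity_type",
    "round_half_up",
]

#: Canonical entity-type identifiers, in reporting order.
ENTITY_TYPES: tuple[str, ...] = ("rare_disease", "disease", "symptom", "sign")

#: Labels emitted into .ann files (upper-case compound form used by the corpus).
BRAT_LABELS: dict[str, str] = {
    "rare_disease": "RAREDISEASE",
    "disease": "DISEASE",
    "symptom": "SYMPTOM",
    "sign": "SIGN",
}

_TYPE_ALIASES: dict[str, str] = {}
for _t in ENTITY_TYPES:
    for _alias in (_t, _t.replace("_", ""), _t.replace("_", " "), _t.replace("_", "-")):
        _TYPE_ALIASES[_alias.lower()] = _t


def normalize_entity_type(label: str) -> str:
    """Map a free-form type label (e.g. ``RAREDISEASE``) onto the canonical vocabulary.

    Raises ``ValueError`` for labels outside the four-type vocabulary.
    """
    key = label.strip().lower()
    if key in _TYPE_ALIASES:
        return _TYPE_ALIASES[key]
    raise ValueError(f"unknown entity type label: {label!r}")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention used in all reports)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Document:
    """A plain-text document identified by ``doc_id``."""

    doc_id: str
    text: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"document {self.doc_id!r} has empty text")


@dataclass(frozen=True)
class EntityMention:
    """A typed entity span, possibly discontinuous (multiple fragments).

    A *grounded* mention carries one or more ``(start, end)`` character
    fragments valid for its document, and its surface equals the document
    slices joined with single spaces. An *ungrounded* mention (a model output
    that could not be located in the text) has no fragments, only a surface.
    """

    fragments: tuple[tuple[int, int], ...]
    entity_type: str
    surface: str
    grounded: bool = True

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"invalid entity type {self.entity_type!r}")
        object.__setattr__(self, "fragments", tuple(tuple(f) for f in self.fragments))
        if self.grounded:
            if not self.fragments:
                raise ValueError("grounded mention requires at least one fragment")
            prev_end = -1
            for start, end in self.fragments:
                if not (0 <= start < end):
                    raise ValueError(f"invalid fragment ({start}, {end})")
                if start < prev_end:
                    raise ValueError("fragments must be sorted and non-overlapping")
                prev_end = end
        else:
            if self.fragments:
                raise ValueError("ungrounded mention must have no fragments")
            if not self.surface:
                raise ValueError("ungrounded mention must have a non-empty surface")

    @property
    def start(self) -> int:
        return self.fragments[0][0]

    @property
    def end(self) -> int:
        return self.fragments[-1][1]

    @property
    def discontinuous(self) -> bool:
        return len(self.fragments) > 1

    def char_span_length(self) -> int:
        return sum(e - s for s, e in self.fragments)

    @classmethod
    def from_document(
        cls, doc: Document, fragments: Sequence[tuple[int, int]], entity_type: str
    ) -> "EntityMention":
        """Build a grounded mention whose surface is read off the document."""
        surface = " ".join(doc.text[s:e] for s, e in fragments)
        return cls(tuple(fragments), entity_type, surface, grounded=True)

    @classmethod
    def ungrounded(cls, surface: str, entity_type: str) -> "EntityMention":
        return cls((), entity_type, surface, grounded=False)

    def validate_against(self, doc: Document) -> None:
        if not self.grounded:
            return
        if self.end > len(doc.text):
            raise ValueError(
                f"mention {self.surface!r} exceeds document {doc.doc_id!r} "
                f"(end {self.end} > length {len(doc.text)})"
            )
        expected = " ".join(doc.text[s:e] for s, e in self.fragments)
        if expected != self.surface:
            raise ValueError(
                f"mention surface {self.surface!r} does not match text slice {expected!r}"
            )


def overlap_chars(a: EntityMention, b: EntityMention) -> int:
    """Number of characters covered by both mentions (union of fragments)."""
    if not (a.grounded and b.grounded):
        return 0
    total = 0
    for s1, e1 in a.fragments:
        for s2, e2 in b.fragments:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


@dataclass
class AnnotationSet:
    """The gold or predicted label set for one document."""

    doc_id: str
    role: Literal["gold", "predicted"]
    mentions: list[EntityMention] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("gold", "predicted"):
            raise ValueError(f"role must be 'gold' or 'predicted', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.mentions)

    def of_type(self, entity_type: str) -> list[EntityMention]:
        return [m for m in self.mentions if m.entity_type == entity_type]

    def validate_against(self, doc: Document) -> None:
        if doc.doc_id != self.doc_id:
            raise ValueError(f"annotation set {self.doc_id!r} vs document {doc.doc_id!r}")
        for m in self.mentions:
            m.validate_against(doc)


class BratParseError(ValueError):
    """Raised for malformed or inconsistent .ann content."""


_T_LINE = re.compile(
    r"^(?P<tid>T\d+)\t(?P<type>\S+) (?P<spans>\d+ \d+(?:;\d+ \d+)*)\t(?P<surface>.*)$"
)


def parse_brat(
    txt_content: str,
    ann_content: str,
    doc_id: str,
    *,
    surface_policy: Literal["strict", "lenient"] = "strict",
    source: str = "",
    warnings: list[str] | None = None,
) -> tuple[Document, AnnotationSet]:
    """Parse a brat standoff ``.txt``/``.ann`` pair into a document and gold annotations.

    Only T (entity) lines are interpreted; relation/event/attribute/note lines
    are ignored. Under the ``strict`` surface policy, a T line whose surface
    field disagrees with the text slice is an error; under ``lenient`` the
    offsets win and a warning is appended to ``warnings``.
    """
    doc = Document(doc_id=doc_id, text=txt_content, source=source)
    mentions: list[EntityMention] = []
    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip() or not line.startswith("T"):
            continue
        m = _T_LINE.match(line)
        if m is None:
            raise BratParseError(f"{doc_id}.ann line {lineno}: malformed T line: {line!r}")
        try:
            etype = normalize_entity_type(m.group("type"))
        except ValueError as exc:
            raise BratParseError(f"{doc_id}.ann line {lineno}: {exc}") from exc
        fragments: list[tuple[int, int]] = []
        for part in m.group("spans").split(";"):
            start_s, end_s = part.split(" ")
            start, end = int(start_s), int(end_s)
            if not (0 <= start < end <= len(txt_content)):
                raise BratParseError(
                    f"{doc_id}.ann line {lineno}: offsets ({start}, {end}) outside "
                    f"text of length {len(txt_content)}"
                )
            fragments.append((start, end))
        fragments.sort()
        slice_surface = " ".join(txt_content[s:e] for s, e in fragments)
        declared = m.group("surface")
        if declared != slice_surface:
            msg = (
                f"{doc_id}.ann line {lineno}: surface {declared!r} differs from "
                f"text slice {slice_surface!r}"
            )
            if surface_policy == "strict":
                raise BratParseError(msg)
            if warnings is not None:
                warnings.append(msg)
        mentions.append(EntityMention(tuple(fragments), etype, slice_surface))
    return doc, AnnotationSet(doc_id=doc_id, role="gold", mentions=mentions)


def write_brat(doc: Document, ann: AnnotationSet) -> str:
    """Serialize an annotation set to .ann content (T lines, start order)."""
    for m in ann.mentions:
        if not m.grounded:
            raise ValueError(f"cannot serialize ungrounded mention {m.surface!r}")
    ann.validate_against(doc)
    lines = []
    for i, m in enumerate(sorted(ann.mentions, key=lambda m: (m.start, m.end)), start=1):
        spans = ";".join(f"{s} {e}" for s, e in m.fragments)
        lines.append(f"T{i}\t{BRAT_LABELS[m.entity_type]} {spans}\t{m.surface}")
    return "\n".join(lines) + ("\n" if lines else "")


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


_TOKEN_RE = re.compile(r"\w+|\S", re.UNICODE)


def tokenize(text: str | Document) -> list[Token]:
    """Split text into maximal letter/digit runs and single punctuation marks.

    Token spans are disjoint, strictly increasing, and cover every non-space
    character, so the original text is recoverable given the gaps.
    """
    if isinstance(text, Document):
        text = text.text
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


@dataclass
class BioSequence:
    """Per-token BIO tags over a tokenized document."""

    tokens: list[Token]
    tags: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags must have equal length")
        prev = "O"
        for i, tag in enumerate(self.tags):
            if tag != "O":
                prefix, _, etype = tag.partition("-")
                if prefix not in ("B", "I") or etype not in ENTITY_TYPES:
                    raise ValueError(f"invalid tag {tag!r} at position {i}")
                if prefix == "I":
                    if prev == "O" or prev.partition("-")[2] != etype:
                        raise ValueError(f"orphan tag {tag!r} at position {i}")
            prev = tag


def to_bio(
    doc: Document,
    ann: AnnotationSet,
    *,
    on_invalid: Literal["error", "drop"] = "error",
) -> BioSequence:
    """Encode continuous, non-overlapping mentions as BIO tags.

    A token is tagged if its span *intersects* the mention (not only if it is
    contained), so partial-token boundary mismatches still tag the token.
    Discontinuous and overlapping mentions cannot be expressed; they raise in
    ``error`` mode and are skipped in ``drop`` mode.
    """
    ann.validate_against(doc)
    tokens = tokenize(doc)
    usable: list[EntityMention] = []
    for m in sorted(ann.mentions, key=lambda m: (m.start, m.end)):
        if m.discontinuous:
            if on_invalid == "error":
                raise ValueError(f"discontinuous mention {m.surface!r} cannot be BIO-encoded")
            continue
        if usable and m.start < usable[-1].end:
            if on_invalid == "error":
                raise ValueError(
                    f"overlapping mentions {usable[-1].surface!r} and {m.surface!r}"
                )
            continue
        usable.append(m)
    tags = ["O"] * len(tokens)
    for m in usable:
        first = True
        for i, tok in enumerate(tokens):
            if tok.start < m.end and tok.end > m.start:  # span intersection
                tags[i] = f"{'B' if first else 'I'}-{m.entity_type}"
                first = False
    return BioSequence(tokens=tokens, tags=tags)


def from_bio(
    doc: Document,
    seq: BioSequence,
    *,
    role: Literal["gold", "predicted"] = "predicted",
) -> AnnotationSet:
    """Decode BIO tags back into mentions (one per maximal B-t I-t* run)."""
    mentions: list[EntityMention] = []
    run_start: int | None = None
    run_end = 0
    run_type = ""

    def flush() -> None:
        nonlocal run_start
        if run_start is not None:
            mentions.append(
                EntityMention.from_document(doc, [(run_start, run_end)], run_type)
            )
            run_start = None

    for tok, tag in zip(seq.tokens, seq.tags):
        if tag == "O":
            flush()
            continue
        prefix, _, etype = tag.partition("-")
        if prefix == "B":
            flush()
            run_start, run_end, run_type = tok.start, tok.end, etype
        else:  # I-: validity guaranteed by BioSequence invariant
            run_end = tok.end
    flush()
    return AnnotationSet(doc_id=doc.doc_id, role=role, mentions=mentions)


def repair_bio(tokens: list[Token], tags: Sequence[str]) -> BioSequence:
    """Lenient constructor: promote orphan I-t tags to B-t, then validate."""
    fixed: list[str] = []
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            etype = tag[2:]
            if prev == "O" or prev.partition("-")[2] != etype:
                tag = "B-" + etype
        fixed.append(tag)
        prev = tag
    return BioSequence(tokens=tokens, tags=fixed)


@dataclass(frozen=True)
class TypeStats:
    total_count: int
    mean_per_doc: float
    sd_per_doc: float


@dataclass(frozen=True)
class CorpusStats:
    n_docs: int
    per_type: dict[str, TypeStats]
    total_mentions: int

    def rounded_rows(self) -> list[dict[str, object]]:
        """Report rows with mean/SD rounded to 2 decimals (half-up)."""
        rows = []
        for etype in ENTITY_TYPES:
            st = self.per_type[etype]
            rows.append(
                {
                    "entity": etype,
                    "total": st.total_count,
                    "mean_per_doc": round_half_up(st.mean_per_doc, 2),
                    "sd_per_doc": round_half_up(st.sd_per_doc, 2),
                }
            )
        return rows


def corpus_stats(
    corpus: Iterable[tuple[Document, AnnotationSet]],
    *,
    ddof: int = 1,
) -> CorpusStats:
    """Per-type totals and per-document mean/SD of mention counts.

    ``ddof=1`` (sample standard deviation) is the default; pass ``ddof=0``
    for the population flavor.
    """
    counts: dict[str, list[int]] = {t: [] for t in ENTITY_TYPES}
    n_docs = 0
    for doc, ann in corpus:
        if ann.role != "gold":
            raise ValueError(f"corpus_stats expects gold annotation sets ({ann.doc_id})")
        ann.validate_against(doc)
        n_docs += 1
        for etype in ENTITY_TYPES:
            counts[etype].append(len(ann.of_type(etype)))
    if n_docs == 0:
        raise ValueError("empty corpus")
    per_type: dict[str, TypeStats] = {}
    for etype, per_doc in counts.items():
        total = sum(per_doc)
        mean = total / n_docs
        if n_docs - ddof > 0:
            var = sum((c - mean) ** 2 for c in per_doc) / (n_docs - ddof)
        else:
            var = 0.0
        per_type[etype] = TypeStats(total, mean, math.sqrt(var))
    return CorpusStats(
        n_docs=n_docs,
        per_type=per_type,
        total_mentions=sum(st.total_count for st in per_type.values()),
    )


def split_corpus(
    doc_ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Deterministic train/validation/test partition.

    Sizes are ``floor(ratio * N)`` for validation and test, with all remainder
    documents assigned to train.
    """
    if any(r < 0 for r in ratios) or not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError(f"ratios must be non-negative and sum to 1, got {ratios}")
    ids = sorted(doc_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate document ids")
    n = len(ids)
    n_groups = sum(1 for r in ratios if r > 0)
    if n < n_groups:
        raise ValueError(f"{n} documents cannot fill {n_groups} non-empty splits")
    rng = random.Random(seed)
    rng.shuffle(ids)
    n_val = int(ratios[1] * n)
    n_test = int(ratios[2] * n)
    n_train = n - n_val - n_test
    return ids[:n_train], ids[n_train : n_train + n_val], ids[n_train + n_val :]


def load_corpus(
    directory: str | Path,
    *,
    surface_policy: Literal["strict", "lenient"] = "strict",
) -> list[tuple[Document, AnnotationSet]]:
    """Read all ``.txt``/``.ann`` basename pairs from a directory."""
    directory = Path(directory)
    corpus = []
    for txt_path in sorted(directory.glob("*.txt")):
        ann_path = txt_path.with_suffix(".ann")
        ann_content = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        corpus.append(
            parse_brat(
                txt_path.read_text(encoding="utf-8"),
                ann_content,
                txt_path.stem,
                surface_policy=surface_policy,
            )
        )
    if not corpus:
        raise FileNotFoundError(f"no .txt documents found under {directory}")
    return corpus


def save_corpus(
    directory: str | Path, corpus: Iterable[tuple[Document, AnnotationSet]]
) -> None:
    """Write each pair as ``<doc_id>.txt`` and ``<doc_id>.ann``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc, ann in corpus:
        (directory / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        (directory / f"{doc.doc_id}.ann").write_text(write_brat(doc, ann), encoding="utf-8")
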