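"""Corpus data model and I/O for EBM sentence classification.

An annotated corpus is a collection of medical abstracts, each a sequence of
pre-segmented sentences.  Every sentence carries one or more gold labels from
the six-way EBM tagset (Background, Intervention, Outcome, Population,
Study Design, Other).  Structured abstracts additionally carry section
headings ("AIM:", "METHODS:", ...) which are detected from the raw sentence
text and propagated downward until the next heading.

The on-disk format is JSONL, one abstract per line::

    {"id": "a1", "sentences": [{"text": "...", "labels": ["Outcome"],
                                "heading": "RESULTS"}]}

``heading`` may be null/absent; labels use the canonical names below.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence


class Label(Enum):
    """The six EBM sentence categories.

    ``Other`` marks non-key sentences; the remaining five are the substantive
    categories clinicians use when judging a trial (PICO-derived plus the
    study-design type).
    """

    BACKGROUND = "Background"
    INTERVENTION = "Intervention"
    OUTCOME = "Outcome"
    POPULATION = "Population"
    STUDY_DESIGN = "Study Design"
    OTHER = "Other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


LABELS: tuple[Label, ...] = tuple(Label)
LABEL_NAMES: tuple[str, ...] = tuple(l.value for l in LABELS)
_NAME_TO_LABEL = {l.value: l for l in LABELS}

KEY_LABELS: tuple[Label, ...] = tuple(l for l in LABELS if l is not Label.OTHER)


def parse_label(name: str) -> Label:
    """Map a canonical label string to a :class:`Label`.

    Raises :class:`CorpusValidationError` for anything outside the six-way
    tagset (e.g. the dropped "Statistics"/"Supposition" categories of earlier
    annotation schemes).
    """
    try:
        return _NAME_TO_LABEL[name]
    except KeyError:
        raise CorpusValidationError(
            f"unknown label {name!r}; expected one of {', '.join(LABEL_NAMES)}"
        ) from None


class CorpusError(Exception):
    """Base class for corpus reading problems."""


class CorpusParseError(CorpusError):
    """Malformed JSON in a corpus file."""


class CorpusValidationError(CorpusError):
    """Well-formed JSON violating the corpus schema or invariants."""


# ---------------------------------------------------------------------------
# Tokenization and POS tagging
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+(?:[-'/.]\w+)*|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Whitespace + punctuation tokenizer; keeps internal hyphens/slashes."""
    return _TOKEN_RE.findall(text)


# Pluggable POS annotator contract: list of surface tokens -> list of tags.
PosTagger = Callable[[Sequence[str]], list[str]]

# Closed-class lexicon for the bundled tagger (lowercased surface -> Penn tag).
_TAG_LEXICON: dict[str, str] = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "each": "DT", "no": "DT", "all": "DT",
    "some": "DT", "any": "DT", "both": "DT",
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "for": "IN",
    "with": "IN", "from": "IN", "into": "IN", "after": "IN", "before": "IN",
    "during": "IN", "between": "IN", "among": "IN", "over": "IN",
    "under": "IN", "than": "IN", "as": "IN", "per": "IN", "versus": "IN",
    "without": "IN", "within": "IN",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "to": "TO",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "has": "VBZ", "have": "VBP", "had": "VBD",
    "do": "VBP", "does": "VBZ", "did": "VBD",
    "can": "MD", "could": "MD", "may": "MD", "might": "MD", "shall": "MD",
    "should": "MD", "will": "MD", "would": "MD", "must": "MD",
    "not": "RB", "also": "RB", "however": "RB", "significantly": "RB",
    "we": "PRP", "they": "PRP", "it": "PRP", "he": "PRP", "she": "PRP",
    "i": "PRP", "you": "PRP",
    "our": "PRP$", "their": "PRP$", "its": "PRP$",
    "which": "WDT", "who": "WP", "whom": "WP", "whose": "WP$", "when": "WRB",
    "where": "WRB", "how": "WRB", "why": "WRB",
    "more": "JJR", "most": "JJS", "less": "JJR", "least": "JJS",
}

_SUFFIX_TAGS: tuple[tuple[str, str], ...] = (
    ("ing", "VBG"), ("ed", "VBD"), ("ly", "RB"),
    ("tion", "NN"), ("sion", "NN"), ("ment", "NN"), ("ness", "NN"),
    ("ity", "NN"), ("ism", "NN"), ("logy", "NN"), ("itis", "NN"),
    ("ous", "JJ"), ("ive", "JJ"), ("ic", "JJ"), ("al", "JJ"), ("able", "JJ"),
    ("ful", "JJ"), ("ant", "JJ"), ("ent", "JJ"), ("est", "JJS"),
    ("s", "NNS"),
)

_NUM_RE = re.compile(r"^[+-]?\d+([.,/]\d+)*%?$")


def default_tagger(tokens: Sequence[str]) -> list[str]:
    """Compact rule-based English POS tagger (Penn-style tags).

    Closed-class words come from a small lexicon; open-class words are tagged
    by suffix heuristics, capitalization and digit patterns, defaulting to NN.
    Accuracy is deliberately modest: features only need a stable, plausible
    tag per surface form, not treebank-grade tagging.
    """
    tags: list[str] = []
    for i, tok in enumerate(tokens):
        low = tok.lower()
        if not tok.strip():
            raise ValueError("empty token cannot be tagged")
        if low in _TAG_LEXICON:
            tags.append(_TAG_LEXICON[low])
        elif _NUM_RE.match(tok):
            tags.append("CD")
        elif not tok[0].isalnum():
            tags.append(tok if tok in {",", ":", "."} else "SYM")
        elif tok[0].isupper() and i > 0:
            tags.append("NNP")
        else:
            for suf, tag in _SUFFIX_TAGS:
                if len(low) > len(suf) + 2 and low.endswith(suf):
                    tags.append(tag)
                    break
            else:
                tags.append("NN")
    return tags


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    surface: str
    pos: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise CorpusValidationError("token surface must be non-empty")


@dataclass
class Sentence:
    """One pre-segmented sentence with its gold annotation.

    ``gold_labels`` is ordered; the first element is the primary label used
    for single-gold confusion matrices.  ``heading`` is the section heading
    governing this sentence (structured abstracts only).
    """

    index: int
    text: str
    tokens: list[Token] = field(default_factory=list)
    heading: str | None = None
    gold_labels: list[Label] = field(default_factory=list)
    predicted_label: Label | None = None

    def __post_init__(self) -> None:
        if self.gold_labels:
            if len(set(self.gold_labels)) != len(self.gold_labels):
                raise CorpusValidationError(
                    f"duplicate gold labels in sentence {self.index}"
                )
            if not 1 <= len(self.gold_labels) <= len(LABELS):
                raise CorpusValidationError("gold label count out of range")

    @property
    def primary_gold(self) -> Label:
        if not self.gold_labels:
            raise CorpusValidationError("sentence has no gold labels")
        return self.gold_labels[0]


@dataclass
class Abstract:
    id: str
    sentences: list[Sentence]
    is_structured: bool = False

    def __post_init__(self) -> None:
        if not self.sentences:
            raise CorpusValidationError(f"abstract {self.id!r} has no sentences")
        for i, s in enumerate(self.sentences):
            if s.index != i:
                raise CorpusValidationError(
                    f"abstract {self.id!r}: sentence index {s.index} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass
class Corpus:
    abstracts: list[Abstract]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [a.id for a in self.abstracts]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise CorpusValidationError(f"duplicate abstract id {dup!r}")

    def __len__(self) -> int:
        return len(self.abstracts)

    def __iter__(self):
        return iter(self.abstracts)

    @property
    def n_sentences(self) -> int:
        return sum(len(a) for a in self.abstracts)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _sentence_from_json(obj: dict, index: int) -> Sentence:
    if "text" not in obj or "labels" not in obj:
        raise CorpusValidationError("sentence record needs 'text' and 'labels'")
    labels = [parse_label(name) for name in obj["labels"]]
    if not labels:
        raise CorpusValidationError("sentence has empty label list")
    return Sentence(
        index=index,
        text=obj["text"],
        heading=obj.get("heading"),
        gold_labels=labels,
    )


def read_corpus(path: str | Path, tagger: PosTagger = default_tagger) -> Corpus:
    """Read a JSONL corpus, tokenize and POS-tag every sentence.

    Raises :class:`CorpusParseError` naming the offending line for malformed
    JSON, :class:`CorpusValidationError` for schema violations (unknown label,
    duplicate abstract id, ...).
    """
    path = Path(path)
    abstracts: list[Abstract] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(
                    f"{path.name}:{lineno}: malformed JSON ({exc.msg})"
                ) from exc
            if "id" not in obj or "sentences" not in obj:
                raise CorpusValidationError(
                    f"{path.name}:{lineno}: abstract record needs 'id' and 'sentences'"
                )
            sentences = [
                _sentence_from_json(s, i) for i, s in enumerate(obj["sentences"])
            ]
            abstract = Abstract(
                id=str(obj["id"]),
                sentences=sentences,
                is_structured=any(s.heading for s in sentences),
            )
            abstracts.append(abstract)
    corpus = Corpus(abstracts=abstracts, provenance=str(path))
    tag_corpus(corpus, tagger)
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the JSONL corpus format (UTF-8, one abstract per line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for abstract in corpus:
            obj = {
                "id": abstract.id,
                "sentences": [
                    {
                        "text": s.text,
                        "labels": [l.value for l in s.gold_labels],
                        "heading": s.heading,
                    }
                    for s in abstract.sentences
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def tag_corpus(corpus: Corpus, tagger: PosTagger = default_tagger) -> Corpus:
    """Tokenize and POS-tag every sentence in place (idempotent)."""
    for abstract in corpus:
        for sent in abstract.sentences:
            surfaces = tokenize(sent.text)
            tags = tagger(surfaces) if surfaces else []
            sent.tokens = [Token(s, t) for s, t in zip(surfaces, tags)]
    return corpus


# ---------------------------------------------------------------------------
# Section heading detection
# ---------------------------------------------------------------------------

# A heading is 1-4 leading tokens, each capitalized or ALL-CAPS (allowing
# "and"/"&"), terminated by a colon at the start of the sentence, e.g.
# "RESULTS:" or "Patients and Methods:".
_HEADING_RE = re.compile(
    r"^\s*((?:(?:[A-Z][A-Za-z]*|and|AND|&)\s+){0,3}(?:[A-Z][A-Za-z]*))\s*:\s*"
)


def match_heading(text: str) -> tuple[str | None, str]:
    """Split ``text`` into (heading or None, remaining content)."""
    m = _HEADING_RE.match(text)
    if not m:
        return None, text
    words = m.group(1).split()
    if not all(w in {"and", "AND", "&"} or w[0].isupper() for w in words):
        return None, text
    return m.group(1), text[m.end():]


def detect_headings(
    abstract: Abstract, tagger: PosTagger = default_tagger
) -> Abstract:
    """Detect section headings and propagate them to following sentences.

    A sentence whose text starts with a heading pattern has the heading
    recorded and stripped from its text and tokens; the heading governs
    every following sentence until the next heading.  A heading-only sentence
    (no content after the colon) is metadata, not a classified sentence: it is
    removed and its heading attached to the sentences below.  Returns a new
    :class:`Abstract`; the input is not modified.
    """
    current: str | None = None
    kept: list[Sentence] = []
    for sent in abstract.sentences:
        heading, rest = match_heading(sent.text)
        if heading is not None:
            current = heading
            if not rest.strip():
                continue  # heading-only line: metadata for what follows
        else:
            rest = sent.text
        surfaces = tokenize(rest)
        tags = tagger(surfaces) if surfaces else []
        kept.append(
            Sentence(
                index=len(kept),
                text=rest.strip(),
                tokens=[Token(s, t) for s, t in zip(surfaces, tags)],
                heading=current,
                gold_labels=list(sent.gold_labels),
                predicted_label=sent.predicted_label,
            )
        )
    if not kept:
        raise CorpusValidationError(
            f"abstract {abstract.id!r} contains only heading lines"
        )
    return Abstract(
        id=abstract.id,
        sentences=kept,
        is_structured=any(s.heading is not None for s in kept),
    )


def detect_headings_corpus(
    corpus: Corpus, tagger: PosTagger = default_tagger
) -> Corpus:
    return Corpus(
        abstracts=[detect_headings(a, tagger) for a in corpus],
        provenance=corpus.provenance,
    )


def partition_corpus(corpus: Corpus) -> tuple[Corpus, Corpus]:
    """Split into (structured S, unstructured U) sub-corpora.

    Every abstract lands in exactly one partition; ``detect_headings`` must
    already have been applied for the split to be meaningful.
    """
    structured = [a for a in corpus if a.is_structured]
    unstructured = [a for a in corpus if not a.is_structured]
    return (
        Corpus(structured, provenance=f"{corpus.provenance} [S]"),
        Corpus(unstructured, provenance=f"{corpus.provenance} [U]"),
    )
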