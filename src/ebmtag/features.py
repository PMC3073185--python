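"""Feature extraction for EBM sentence classification.

Each sentence is mapped to a sparse binary feature set drawn from four
families:

* **lexical** — unigrams and bigrams, each carrying the token's POS tag;
* **semantic** — concept identifiers (CUIs) from a thesaurus lookup per
  token, their synonym strings (whole or broken into single words), and CUIs
  from a pre-computed concept-annotation table (a file-backed stand-in for a
  MetaMap run);
* **structural** — sentence position within the abstract and the governing
  section heading, either raw or mapped to one of four rhetorical roles
  (Aim, Method, Results, Conclusions);
* **sequential** — indirect (features of up to three previous sentences,
  positionally prefixed), windowed (previous + next sentence), and direct
  (predicted labels of previous sentences, from a stacked base learner).

Feature names are namespaced by family prefix so no two families collide.
Extraction is a pure function of (abstract, config, resources).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

from .corpus import Abstract, Label, Sentence

logger = logging.getLogger(__name__)

BOS = "<BOS>"
EOS = "<EOS>"

FeatureVector = frozenset  # of feature-name strings (binary presence)

DirectWindow = Literal[0, 1, 3, "all"]
HeadingMode = Literal["none", "raw", "mapped"]


@dataclass(frozen=True)
class FeatureConfig:
    """Declarative switch-set naming which feature families are active."""

    use_unigram_pos: bool = False
    use_bigram_pos: bool = False
    use_token_cui: bool = False
    use_token_syn: bool = False
    use_token_syn_b: bool = False
    use_metamap_cui: bool = False
    use_position: bool = False
    heading_mode: HeadingMode = "none"
    indirect_window: int = 0
    use_windowed: bool = False
    direct_window: DirectWindow = 0
    preset_name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.indirect_window <= 3:
            raise ValueError("indirect_window must be in 0..3")
        if self.direct_window not in (0, 1, 3, "all"):
            raise ValueError("direct_window must be one of 0, 1, 3, 'all'")

    @property
    def needs_thesaurus(self) -> bool:
        return self.use_token_cui or self.use_token_syn or self.use_token_syn_b

    @property
    def needs_base_model(self) -> bool:
        return self.direct_window != 0


@dataclass
class Thesaurus:
    """Token -> concept ids -> synonym strings (a UMLS-like lookup table)."""

    token_to_cuis: dict[str, frozenset[str]] = field(default_factory=dict)
    cui_to_synonyms: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for token, cuis in self.token_to_cuis.items():
            for cui in cuis:
                self.cui_to_synonyms.setdefault(cui, frozenset())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Thesaurus":
        """Load from TSV with columns: token, cui, pipe-separated synonyms."""
        token_to_cuis: dict[str, set[str]] = {}
        cui_to_syn: dict[str, set[str]] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                token, cui = row[0].lower(), row[1]
                syns = [s for s in (row[2].split("|") if len(row) > 2 else []) if s]
                token_to_cuis.setdefault(token, set()).add(cui)
                cui_to_syn.setdefault(cui, set()).update(syns)
        return cls(
            token_to_cuis={t: frozenset(c) for t, c in token_to_cuis.items()},
            cui_to_synonyms={c: frozenset(s) for c, s in cui_to_syn.items()},
        )

    def cuis_for(self, token: str) -> frozenset[str]:
        return self.token_to_cuis.get(token.lower(), frozenset())


class MissingAnnotationError(KeyError):
    """A concept-annotation record required by the config is absent."""


@dataclass
class ConceptAnnotations:
    """Pre-computed per-sentence concept ids keyed by (abstract id, index)."""

    by_sentence: dict[tuple[str, int], frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConceptAnnotations":
        """Columns: abstract_id, sentence_index, pipe-separated cuis."""
        table: dict[tuple[str, int], frozenset[str]] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                cuis = [c for c in (row[2].split("|") if len(row) > 2 else []) if c]
                table[(row[0], int(row[1]))] = frozenset(cuis)
        return cls(by_sentence=table)

    def cuis_for(self, abstract_id: str, index: int) -> frozenset[str]:
        try:
            return self.by_sentence[(abstract_id, index)]
        except KeyError:
            raise MissingAnnotationError(
                f"no concept annotation for sentence ({abstract_id!r}, {index})"
            ) from None


@dataclass
class Resources:
    """External lookup tables demanded by some feature families."""

    thesaurus: Thesaurus | None = None
    annotations: ConceptAnnotations | None = None
    heading_map: Mapping[str, str] | None = None  # normalized heading -> role


# ---------------------------------------------------------------------------
# Heading-role mapping
# ---------------------------------------------------------------------------

ROLES = ("Aim", "Method", "Results", "Conclusions")


def normalize_heading(heading: str) -> str:
    """Uppercase, strip the trailing colon, collapse internal whitespace."""
    return " ".join(heading.rstrip(":").upper().split())


def load_heading_map(path: str | Path | None = None) -> dict[str, str]:
    """Load the heading-string -> rhetorical-role table (bundled by default)."""
    if path is None:
        ref = importlib_resources.files("ebmtag.data") / "heading_roles.tsv"
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    mapping: dict[str, str] = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        heading, role = normalize_heading(row[0]), row[1].strip()
        if role not in ROLES:
            raise ValueError(f"unknown rhetorical role {role!r} for {heading!r}")
        mapping[heading] = role
    return mapping


_HEADING_MAP_CACHE: dict[str, str] | None = None


def _bundled_heading_map() -> dict[str, str]:
    global _HEADING_MAP_CACHE
    if _HEADING_MAP_CACHE is None:
        _HEADING_MAP_CACHE = load_heading_map()
    return _HEADING_MAP_CACHE


# ---------------------------------------------------------------------------
# Feature families
# ---------------------------------------------------------------------------


def lexical_features(sentence: Sentence, config: FeatureConfig) -> FeatureVector:
    """Unigram ("U=word_POS") and bigram ("B=w1_p1__w2_p2") features."""
    feats: set[str] = set()
    toks = sentence.tokens
    if config.use_unigram_pos:
        feats.update(f"U={t.surface.lower()}_{t.pos}" for t in toks)
    if config.use_bigram_pos:
        feats.update(
            f"B={a.surface.lower()}_{a.pos}__{b.surface.lower()}_{b.pos}"
            for a, b in zip(toks, toks[1:])
        )
    return frozenset(feats)


def _unigram_features(sentence: Sentence) -> FeatureVector:
    return lexical_features(sentence, FeatureConfig(use_unigram_pos=True))


def semantic_features(
    sentence: Sentence,
    thesaurus: Thesaurus,
    config: FeatureConfig,
    annotations: ConceptAnnotations | None = None,
    abstract_id: str | None = None,
) -> FeatureVector:
    """Concept-based features from thesaurus lookups and annotation tables.

    Every concept id of an ambiguous token is emitted (no disambiguation).
    A token absent from the thesaurus contributes nothing; a missing record
    in the annotation table under ``use_metamap_cui`` raises
    :class:`MissingAnnotationError` rather than silently yielding nothing.
    """
    feats: set[str] = set()
    if config.use_token_cui or config.use_token_syn or config.use_token_syn_b:
        for tok in sentence.tokens:
            for cui in thesaurus.cuis_for(tok.surface):
                if config.use_token_cui:
                    feats.add(f"CUI={cui}")
                if config.use_token_syn or config.use_token_syn_b:
                    for syn in thesaurus.cui_to_synonyms.get(cui, frozenset()):
                        if config.use_token_syn:
                            feats.add(f"SYN={syn.lower()}")
                        if config.use_token_syn_b:
                            feats.update(f"SYNB={w.lower()}" for w in syn.split())
    if config.use_metamap_cui:
        if annotations is None:
            raise MissingAnnotationError(
                "use_metamap_cui requires a concept-annotation table"
            )
        for cui in annotations.cuis_for(abstract_id or "", sentence.index):
            feats.add(f"MM={cui}")
    return frozenset(feats)


MAX_ABS_POSITION = 10  # absolute 1-based sentence index is capped here


def structural_features(
    sentence: Sentence,
    abstract: Abstract,
    config: FeatureConfig,
    heading_map: Mapping[str, str] | None = None,
) -> FeatureVector:
    """Position and section-heading features.

    Position is encoded both as the capped absolute 1-based index
    ("POSN=3") and as a decile-relative bucket ("RELPOS=2"), so short and
    long abstracts share a comparable encoding.  Heading features are only
    emitted inside structured abstracts; under mapped mode an unmapped
    heading falls back to "SECM=Other" with a warning.
    """
    feats: set[str] = set()
    if config.use_position:
        n = len(abstract.sentences)
        feats.add(f"POSN={min(sentence.index + 1, MAX_ABS_POSITION)}")
        feats.add(f"RELPOS={(10 * sentence.index) // n}")
    if config.heading_mode != "none" and sentence.heading is not None:
        norm = normalize_heading(sentence.heading)
        if config.heading_mode == "raw":
            feats.add(f"SEC={norm}")
        else:
            mapping = heading_map if heading_map is not None else _bundled_heading_map()
            role = mapping.get(norm)
            if role is None:
                logger.warning("heading %r not in role map; using Other", norm)
                role = "Other"
            feats.add(f"SECM={role}")
    return frozenset(feats)


def indirect_sequential_features(
    abstract: Abstract, i: int, k: int
) -> FeatureVector:
    """Unigram features of the previous ``k`` sentences, prefixed "Pj_".

    Offsets running past the start of the abstract emit the begin-of-sequence
    sentinel "Pj_<BOS>".
    """
    if not 1 <= k <= 3:
        raise ValueError("indirect window must be 1..3")
    feats: set[str] = set()
    for j in range(1, k + 1):
        if i - j < 0:
            feats.add(f"P{j}_{BOS}")
        else:
            prev = _unigram_features(abstract.sentences[i - j])
            feats.update(f"P{j}_{f}" for f in prev)
    return frozenset(feats)


def windowed_features(abstract: Abstract, i: int) -> FeatureVector:
    """Unigram features of the previous ("P1_") and next ("NX_") sentence."""
    feats: set[str] = set()
    if i == 0:
        feats.add(f"P1_{BOS}")
    else:
        feats.update(f"P1_{f}" for f in _unigram_features(abstract.sentences[i - 1]))
    if i == len(abstract.sentences) - 1:
        feats.add(f"NX_{EOS}")
    else:
        feats.update(f"NX_{f}" for f in _unigram_features(abstract.sentences[i + 1]))
    return frozenset(feats)


def direct_sequential_features(
    predicted: Sequence[Label], i: int, window: DirectWindow
) -> FeatureVector:
    """Features from the predicted labels of previous sentences (stacking).

    ``predicted`` holds the base learner's labels for sentences ``0..i-1``.
    ``window=1`` emits "PLAB1=<label>"; ``window=3`` emits "PLAB1..PLAB3";
    ``window='all'`` emits positional features back to the start plus an
    order-free bag "PLABANY=<label>".  Out-of-range offsets emit sentinels.
    """
    if window == 0:
        return frozenset()
    feats: set[str] = set()
    span = i if window == "all" else int(window)
    span = max(span, 1)  # at i=0 even window='all' emits the PLAB1 sentinel
    for j in range(1, span + 1):
        if i - j < 0:
            feats.add(f"PLAB{j}={BOS}")
        else:
            feats.add(f"PLAB{j}={predicted[i - j].value}")
    if window == "all":
        feats.update(f"PLABANY={lab.value}" for lab in predicted[:i])
    return frozenset(feats)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_BASE = dict(use_unigram_pos=True, use_position=True, heading_mode="raw")

_PRESETS: dict[str, dict] = {
    "1.P": dict(use_unigram_pos=True),
    "2.P": dict(use_bigram_pos=True),
    "1.P+2.P": dict(use_unigram_pos=True, use_bigram_pos=True),
    "1.P+Pst": dict(use_unigram_pos=True, use_position=True),
    "1.P+Pst+W": dict(use_unigram_pos=True, use_position=True, use_windowed=True),
    "1.P+Pst+Sec+W": dict(
        use_unigram_pos=True, use_position=True, heading_mode="raw", use_windowed=True
    ),
    "1.P+Sec": dict(use_unigram_pos=True, heading_mode="raw"),
    "1.P+Sec_M": dict(use_unigram_pos=True, heading_mode="mapped"),
    "1.P+Pst+Sec": dict(use_unigram_pos=True, use_position=True, heading_mode="raw"),
    "1.P+Pst+Sec_M": dict(
        use_unigram_pos=True, use_position=True, heading_mode="mapped"
    ),
    "Token-CUI": dict(use_token_cui=True),
    "Token-Syn": dict(use_token_syn=True),
    "Token-Syn-B": dict(use_token_syn_b=True),
    "MetaMap-CUI": dict(use_metamap_cui=True),
    "1.P+T-CUI": dict(use_unigram_pos=True, use_token_cui=True),
    "1.P+T-Syn": dict(use_unigram_pos=True, use_token_syn=True),
    "1.P+T-Syn-B": dict(use_unigram_pos=True, use_token_syn_b=True),
    "1.P+T-CUI+T-Syn": dict(
        use_unigram_pos=True, use_token_cui=True, use_token_syn=True
    ),
    "1.P+T-CUI+T-Syn-B": dict(
        use_unigram_pos=True, use_token_cui=True, use_token_syn_b=True
    ),
    "B": dict(**_BASE),
    "B+Window": dict(**_BASE, use_windowed=True),
    "B+1 Prev. Sen.": dict(**_BASE, indirect_window=1),
    "B+2 Prev. Sen.": dict(**_BASE, indirect_window=2),
    "B+3 Prev. Sen.": dict(**_BASE, indirect_window=3),
    "B+1 Prev. Label": dict(**_BASE, direct_window=1),
    "B+3 Prev Labels": dict(**_BASE, direct_window=3),
    "B+All Prev Labels": dict(**_BASE, direct_window="all"),
}


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def build_preset(name: str) -> FeatureConfig:
    """Return the named feature configuration.

    "B" is the basic set: unigrams with POS, position, and raw section
    headings (inert on unstructured abstracts).  The "+N Prev. Sen." presets
    add indirect sequential features, "+... Prev Label(s)" the stacked direct
    ones, "+W"/"+Window" the previous/next-sentence window.
    """
    try:
        switches = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}"
        ) from None
    return FeatureConfig(preset_name=name, **switches)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_sequence(
    abstract: Abstract,
    config: FeatureConfig,
    resources: Resources | None = None,
    base_predictions: Sequence[Label] | None = None,
) -> list[FeatureVector]:
    """One feature vector per sentence: the union of all enabled families.

    ``base_predictions`` supplies the stacked base learner's labels when
    direct sequential features are active; omitting it in that case is an
    error (gold labels are never substituted).
    """
    resources = resources or Resources()
    if config.needs_thesaurus and resources.thesaurus is None:
        raise ValueError(f"config {config.preset_name or ''} requires a thesaurus")
    if config.use_metamap_cui and resources.annotations is None:
        raise MissingAnnotationError(
            "config requires a concept-annotation table"
        )
    if config.needs_base_model and base_predictions is None:
        raise ValueError("direct sequential features require base predictions")
    if base_predictions is not None and len(base_predictions) != len(
        abstract.sentences
    ):
        raise ValueError("base_predictions length must match the abstract")

    vectors: list[FeatureVector] = []
    for sent in abstract.sentences:
        feats: set[str] = set()
        feats |= lexical_features(sent, config)
        if config.needs_thesaurus or config.use_metamap_cui:
            feats |= semantic_features(
                sent,
                resources.thesaurus or Thesaurus(),
                config,
                annotations=resources.annotations,
                abstract_id=abstract.id,
            )
        feats |= structural_features(
            sent, abstract, config, heading_map=resources.heading_map
        )
        if config.indirect_window > 0:
            feats |= indirect_sequential_features(
                abstract, sent.index, config.indirect_window
            )
        if config.use_windowed:
            feats |= windowed_features(abstract, sent.index)
        if config.direct_window != 0:
            feats |= direct_sequential_features(
                base_predictions, sent.index, config.direct_window
            )
        vectors.append(frozenset(feats))
    return vectors
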