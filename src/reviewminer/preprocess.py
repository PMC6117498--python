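"""Text preprocessing: segmentation hook, POS filtering, stopwords, synonym
canonicalization and rule-based entity placeholder substitution.

The original reviews are Chinese and require a statistical segmenter with
part-of-speech output; segmentation quality is not this package's concern, so
the tokenizer is a pluggable hook (any callable ``text -> tokens`` or
``text -> (tokens, pos_tags)``) with a whitespace default, keeping the pipeline
language-agnostic.  Entity mentions with many surface forms (temperatures,
ages, money amounts, ...) are collapsed onto a single placeholder token such as
``#BODY_TEMPERATURE#`` so that sparse mentions pool into one vocabulary item.

Pipeline order: segment -> pos_filter -> remove_stopwords -> replace_entities
-> replace_synonyms.  Entity rules run before the thesaurus so that entity
surface variants never depend on thesaurus coverage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from .corpus_io import Corpus, Review

_DATA_PACKAGE = "reviewminer.data"

#: Placeholder inventory; placeholders are never themselves rewritten.
PLACEHOLDERS = (
    "#BODY_TEMPERATURE#", "#AGE#", "#NUMBER#", "#HEIGHT#", "#WEIGHT#",
    "#DATE#", "#LOCATION#", "#MONEY#", "#ORGANIZATION#", "#PERCENT#",
    "#PERSON#", "#TIME#",
)

#: Content-word POS tags retained by default (nouns, verbs, adjectives, adverbs).
DEFAULT_KEEP_TAGS = frozenset({"n", "v", "a", "d"})


def _data_path(name: str):
    return resources.files(_DATA_PACKAGE).joinpath(name)


# ---------------------------------------------------------------------------
# Segmentation and filtering
# ---------------------------------------------------------------------------

def whitespace_tokenizer(text: str) -> list[str]:
    return text.split()


def segment(
    raw_text: str,
    tokenizer: Optional[Callable] = None,
) -> tuple[list[str], Optional[list[str]]]:
    """Split raw text into tokens via the pluggable tokenizer hook.

    The hook may return either a token list or a ``(tokens, pos_tags)`` pair;
    tags, when provided, must parallel the tokens.
    """
    if tokenizer is None:
        tokenizer = whitespace_tokenizer
    out = tokenizer(raw_text)
    if isinstance(out, tuple):
        tokens, tags = out
        tokens, tags = list(tokens), list(tags)
        if len(tags) != len(tokens):
            raise ValueError(
                f"tokenizer returned {len(tags)} tags for {len(tokens)} tokens"
            )
        return tokens, tags
    return list(out), None


def pos_filter(
    tokens: Sequence[str],
    pos_tags: Optional[Sequence[str]],
    keep: Iterable[str] = DEFAULT_KEEP_TAGS,
) -> list[str]:
    """Keep the subsequence of tokens whose POS tag is in ``keep``."""
    if pos_tags is None:
        raise ValueError(
            "pos_filter requires pos_tags; disable POS filtering when the "
            "tokenizer provides none"
        )
    if len(pos_tags) != len(tokens):
        raise ValueError("pos_tags must parallel tokens")
    keep = set(keep)
    return [t for t, tag in zip(tokens, pos_tags) if tag in keep]


def remove_stopwords(tokens: Sequence[str], stoplist: Iterable[str]) -> list[str]:
    """Drop stoplist members (case-sensitive exact match), preserving order."""
    stop = set(stoplist)
    return [t for t in tokens if t not in stop]


# ---------------------------------------------------------------------------
# Thesaurus and entity rules
# ---------------------------------------------------------------------------

@dataclass
class ThesaurusMap:
    """Functional variant -> canonical mapping; idempotent by construction."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        # Idempotence: a canonical that appears as a variant must map to itself.
        for variant, canon in self.mapping.items():
            target = self.mapping.get(canon)
            if target is not None and target != canon:
                raise ValueError(
                    f"thesaurus not idempotent: {variant!r} -> {canon!r} -> {target!r}"
                )

    def canonical(self, token: str) -> str:
        return self.mapping.get(token, token)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class EntityRuleSet:
    """Ordered whole-token regex rules mapping surfaces to placeholders.

    The first matching rule wins; placeholder tokens are never rewritten.
    """

    rules: list[tuple[re.Pattern, str]] = field(default_factory=list)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "EntityRuleSet":
        compiled = []
        for pattern, placeholder in pairs:
            try:
                compiled.append((re.compile(pattern), placeholder))
            except re.error as exc:
                raise ValueError(f"malformed entity pattern {pattern!r}: {exc}")
        return cls(compiled)

    def apply(self, token: str) -> str:
        if token in PLACEHOLDERS:
            return token
        for pattern, placeholder in self.rules:
            if pattern.fullmatch(token):
                return placeholder
        return token


def replace_synonyms(tokens: Sequence[str], thesaurus: ThesaurusMap) -> list[str]:
    """Map each token to its canonical form; unmapped tokens pass through."""
    return [thesaurus.canonical(t) for t in tokens]


def replace_entities(tokens: Sequence[str], rules: EntityRuleSet) -> list[str]:
    """Replace entity surface forms with placeholder tokens, length-preserving."""
    return [rules.apply(t) for t in tokens]


def load_stopwords(path: str | Path | None = None) -> set[str]:
    """One stopword per line; ``None`` loads the packaged default list."""
    text = (_data_path("stopwords.txt").read_text(encoding="utf-8")
            if path is None else Path(path).read_text(encoding="utf-8"))
    return {line.strip() for line in text.splitlines() if line.strip()}


def load_thesaurus(path: str | Path | None = None) -> ThesaurusMap:
    """TSV ``variant<TAB>canonical``; ``None`` loads the packaged default."""
    text = (_data_path("thesaurus.tsv").read_text(encoding="utf-8")
            if path is None else Path(path).read_text(encoding="utf-8"))
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"thesaurus line {lineno}: expected 2 columns")
        mapping[parts[0].strip()] = parts[1].strip()
    return ThesaurusMap(mapping)


def load_entity_rules(path: str | Path | None = None) -> EntityRuleSet:
    """TSV ``pattern<TAB>placeholder``; ``None`` loads the packaged rules."""
    text = (_data_path("entity_rules.tsv").read_text(encoding="utf-8")
            if path is None else Path(path).read_text(encoding="utf-8"))
    pairs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"entity rules line {lineno}: expected 2 columns")
        pairs.append((parts[0], parts[1].strip()))
    return EntityRuleSet.from_pairs(pairs)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def preprocess_tokens(
    tokens: Sequence[str],
    pos_tags: Optional[Sequence[str]] = None,
    *,
    keep_tags: Optional[Iterable[str]] = DEFAULT_KEEP_TAGS,
    stopwords: Optional[Iterable[str]] = None,
    entity_rules: Optional[EntityRuleSet] = None,
    thesaurus: Optional[ThesaurusMap] = None,
) -> list[str]:
    """POS-filter, stop, entity-substitute and canonicalize a token sequence.

    POS filtering is applied only when tags are available and ``keep_tags`` is
    not ``None``; the other stages are skipped when their resource is ``None``.
    """
    out = list(tokens)
    if pos_tags is not None and keep_tags is not None:
        out = pos_filter(out, pos_tags, keep_tags)
    if stopwords is not None:
        out = remove_stopwords(out, stopwords)
    if entity_rules is not None:
        out = replace_entities(out, entity_rules)
    if thesaurus is not None:
        out = replace_synonyms(out, thesaurus)
    return out


def preprocess_corpus(
    corpus: Corpus,
    *,
    tokenizer: Optional[Callable] = None,
    keep_tags: Optional[Iterable[str]] = DEFAULT_KEEP_TAGS,
    stopwords: Optional[Iterable[str]] = None,
    entity_rules: Optional[EntityRuleSet] = None,
    thesaurus: Optional[ThesaurusMap] = None,
) -> Corpus:
    """Run the full pipeline over a corpus, returning a new tokenized corpus.

    Reviews that already carry tokens keep them (segmentation is skipped);
    raw-text-only reviews are segmented first.
    """
    out: list[Review] = []
    for r in corpus:
        if r.tokens is not None:
            tokens, tags = list(r.tokens), r.pos_tags
        else:
            tokens, tags = segment(r.raw_text or "", tokenizer)
        cleaned = preprocess_tokens(
            tokens, tags, keep_tags=keep_tags, stopwords=stopwords,
            entity_rules=entity_rules, thesaurus=thesaurus,
        )
        out.append(Review(
            doc_id=r.doc_id, raw_text=r.raw_text, tokens=cleaned,
            labels=set(r.labels) if r.labels is not None else None,
            disease=r.disease, hospital_level=r.hospital_level,
            doctor_id=r.doctor_id,
        ))
    return Corpus(out)


# ---------------------------------------------------------------------------
# Vocabulary and bag-of-words
# ---------------------------------------------------------------------------

class Vocabulary:
    """Dense token <-> index bijection in first-appearance order."""

    def __init__(self, tokens: Sequence[str]):
        self._index: dict[str, int] = {}
        for t in tokens:
            if t in self._index:
                raise ValueError(f"duplicate token {t!r} in vocabulary")
            self._index[t] = len(self._index)
        self._tokens = list(tokens)

    @property
    def V(self) -> int:
        return len(self._tokens)

    def __len__(self) -> int:
        return self.V

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def index(self, token: str) -> int:
        return self._index[token]

    def token(self, idx: int) -> str:
        return self._tokens[idx]

    @property
    def tokens(self) -> list[str]:
        return list(self._tokens)


def build_vocabulary(corpus: Corpus, min_count: int = 1) -> Vocabulary:
    """Index tokens with corpus frequency >= ``min_count`` in first-appearance
    order (deterministic)."""
    counts: dict[str, int] = {}
    order: list[str] = []
    for r in corpus:
        if r.tokens is None:
            raise ValueError(f"review {r.doc_id!r} has no tokens; preprocess first")
        for t in r.tokens:
            if t not in counts:
                counts[t] = 0
                order.append(t)
            counts[t] += 1
    kept = [t for t in order if counts[t] >= min_count]
    if not kept:
        raise ValueError(f"no token reaches min_count={min_count}")
    return Vocabulary(kept)


def docs_to_bow(corpus: Corpus, vocab: Vocabulary) -> list[list[int]]:
    """Per-document token-index sequences; out-of-vocabulary tokens dropped,
    sequence order preserved."""
    bows = []
    for r in corpus:
        toks = r.tokens or []
        bows.append([vocab.index(t) for t in toks if t in vocab])
    return bows
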