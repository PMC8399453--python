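"""Text cleaning for patent abstract fields.

A raw free-text field (``Novelty`` or ``Use``) is turned into an ordered
stream of lowercase lemmas in four steps, applied in this order:

1. lowercase, strip punctuation, digits and math symbols (tokenize);
2. stop-word removal;
3. lemmatization;
4. common-word removal (generic patent-prose words that carry no
   domain-specific context).

Hyphenated compounds such as ``beta-cyclodextrin`` survive as single
tokens.  The lemmatizer is a deterministic rule-based English scheme
(noun-plural rules first, verb-inflection rules as fallback); its
identifier is recorded in run metadata so results can be tied to the
normalization that produced them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "CleanConfig",
    "TokenStream",
    "clean_text",
    "preprocess_corpus",
    "lemmatize",
    "default_stopwords",
    "default_commonwords",
]

LEMMATIZER_ID = "rule_en_v1"

_TOKEN_RE = re.compile(r"[a-z]+(?:-[a-z]+)*")
_VOWELS = set("aeiou")

_IRREGULAR_NOUNS = {
    "children": "child",
    "men": "man",
    "women": "woman",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
    "geese": "goose",
    "analyses": "analysis",
    "matrices": "matrix",
    "media": "medium",
    "criteria": "criterion",
    "phenomena": "phenomenon",
}


def _undouble(stem: str) -> str:
    if (
        len(stem) >= 3
        and stem[-1] == stem[-2]
        and stem[-1] not in _VOWELS
        and stem[-1] not in "lsz"
    ):
        return stem[:-1]
    return stem


def _cvc(stem: str) -> bool:
    """Consonant-vowel-consonant ending: the classic cue for a dropped 'e'."""
    if len(stem) == 2:  # e.g. "us" from "using"
        return stem[0] in _VOWELS and stem[1] not in _VOWELS and stem[1] not in "wxy"
    if len(stem) < 3:
        return False
    c2, v, c1 = stem[-3], stem[-2], stem[-1]
    return c1 not in _VOWELS and c1 not in "wxy" and v in _VOWELS and c2 not in _VOWELS


def lemmatize(word: str) -> str:
    """Map an inflected English word to its base form.

    Dictionary-free rule scheme: irregular plurals, then regular noun
    plurals, then verb -ing/-ed endings.  Deterministic and conservative
    (a word that matches no rule is returned unchanged).
    """
    if word in _IRREGULAR_NOUNS:
        return _IRREGULAR_NOUNS[word]
    # noun plurals
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("sses", "shes", "ches", "xes", "zes")) and len(word) > 4:
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")) and len(word) > 3:
        return word[:-1]
    # verb inflections
    if word.endswith("ing") and len(word) >= 5:
        stem = word[:-3]
        stem = _undouble(stem)
        if _cvc(stem):
            stem += "e"
        return stem
    if word.endswith("ed") and len(word) > 4:
        stem = word[:-2]
        if stem.endswith("i"):
            return stem[:-1] + "y"
        stem = _undouble(stem)
        if _cvc(stem):
            stem += "e"
        return stem
    return word


def _load_wordlist(source) -> set[str]:
    words: set[str] = set()
    for line in str(source).splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return words


def _read_data(name: str) -> str:
    return resources.files("patentscape.data").joinpath(name).read_text("utf-8")


def default_stopwords() -> set[str]:
    """The bundled English stop-word list."""
    return _load_wordlist(_read_data("stopwords.txt"))


def default_commonwords() -> set[str]:
    """The bundled generic patent-prose word list, lemmatized."""
    return {lemmatize(w) for w in _load_wordlist(_read_data("commonwords.txt"))}


@dataclass
class CleanConfig:
    """Parameters of the cleaning pipeline.

    Both word lists must be lowercase; the common-word list is compared
    against lemmas (it is applied after lemmatization), so entries are
    lemmatized when loaded from file.
    """

    stopwords: set[str] = field(default_factory=default_stopwords)
    common_words: set[str] = field(default_factory=default_commonwords)
    lemmatizer_id: str = LEMMATIZER_ID
    min_token_length: int = 2

    @classmethod
    def from_files(
        cls,
        stopwords_path: str | Path | None = None,
        commonwords_path: str | Path | None = None,
        min_token_length: int = 2,
    ) -> "CleanConfig":
        stop = (
            _load_wordlist(Path(stopwords_path).read_text("utf-8"))
            if stopwords_path
            else default_stopwords()
        )
        common = (
            {lemmatize(w) for w in _load_wordlist(Path(commonwords_path).read_text("utf-8"))}
            if commonwords_path
            else default_commonwords()
        )
        return cls(stopwords=stop, common_words=common, min_token_length=min_token_length)


@dataclass
class TokenStream:
    """Ordered lowercase lemmas from one source field of one record."""

    tokens: list[str]
    source_field: str = "novelty"

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def tokenize(raw: str, min_token_length: int = 2) -> list[str]:
    """Lowercase and split on non-alphabetic characters, keeping
    in-word hyphens (``beta-cyclodextrin`` stays whole)."""
    return [t for t in _TOKEN_RE.findall(raw.lower()) if len(t) >= min_token_length]


def clean_text(raw: str, cfg: CleanConfig | None = None, source_field: str = "novelty") -> TokenStream:
    """Run the four-step cleaning pipeline on one text field."""
    if cfg is None:
        cfg = CleanConfig()
    tokens = tokenize(raw, cfg.min_token_length)
    tokens = [t for t in tokens if t not in cfg.stopwords]
    tokens = [lemmatize(t) for t in tokens]
    tokens = [t for t in tokens if t not in cfg.common_words]
    return TokenStream(tokens=tokens, source_field=source_field)


def preprocess_corpus(
    corpus: Iterable,
    field_name: str = "novelty",
    cfg: CleanConfig | None = None,
) -> dict[str, TokenStream]:
    """Clean one text field for every record.

    Records whose stream comes out empty are retained with empty streams;
    they are excluded later, at vectorization, where normalization would
    be undefined.
    """
    if field_name not in ("novelty", "use"):
        raise ValueError(f"field must be 'novelty' or 'use', got {field_name!r}")
    if cfg is None:
        cfg = CleanConfig()
    out: dict[str, TokenStream] = {}
    for rec in corpus:
        raw = rec.novelty_text if field_name == "novelty" else rec.use_text
        out[rec.patent_id] = clean_text(raw or "", cfg, source_field=field_name)
    return out
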