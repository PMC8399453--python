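"""Dosage-form trend mining.

Patents are matched against a lexicon of pharmaceutical dosage forms
(tablet, solution, gel, patch, ...), each form backed by one or more
query terms — single lemmas or multi-word phrases in the spirit of the
U.S. Pharmacopeia form definitions.  Matching runs over the same cleaned
lemma stream used by the rest of the pipeline, so it is case- and
inflection-insensitive (tablet/tablets/Tablet all hit), and phrases must
appear as consecutive cleaned tokens.  Counts are per patent: a patent
matching a form through three different terms still counts once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .corpus import PatentRecord
from .preprocess import CleanConfig, clean_text

__all__ = [
    "DosageFormLexicon",
    "TrendSeries",
    "match_dosage_forms",
    "trend_series",
    "default_lexicon",
]

logger = logging.getLogger(__name__)


@dataclass
class DosageFormLexicon:
    """Form name -> set of query terms (each a lemma or a phrase)."""

    forms: dict[str, set[str]]

    def __post_init__(self) -> None:
        for form, terms in self.forms.items():
            if not terms:
                raise ValueError(f"form {form!r} has an empty term set")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DosageFormLexicon":
        df = pd.read_csv(path, sep="\t", dtype=str)
        forms: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            forms.setdefault(row["form"], set()).add(row["term"].strip().lower())
        return cls(forms=forms)


def default_lexicon() -> DosageFormLexicon:
    """The bundled 14-form lexicon with synonym seeds; override with your
    own TSV (columns ``form``, ``term``) for a production analysis."""
    with resources.as_file(resources.files("patentscape.data").joinpath("dosage_forms.tsv")) as p:
        return DosageFormLexicon.from_tsv(p)


def _clean_term(term: str, cfg: CleanConfig) -> tuple[str, ...]:
    """A query term passes through the same cleaning pipeline as the text,
    except the common-word filter (a form word must stay matchable even
    if a user's common list contains it)."""
    stripped = CleanConfig(
        stopwords=cfg.stopwords,
        common_words=set(),
        lemmatizer_id=cfg.lemmatizer_id,
        min_token_length=cfg.min_token_length,
    )
    return tuple(clean_text(term, stripped).tokens)


def _contains_phrase(tokens: list[str], phrase: tuple[str, ...]) -> bool:
    if not phrase:
        return False
    if len(phrase) == 1:
        return phrase[0] in tokens
    k = len(phrase)
    return any(tuple(tokens[i : i + k]) == phrase for i in range(len(tokens) - k + 1))


def match_dosage_forms(
    record: PatentRecord,
    lexicon: DosageFormLexicon,
    cfg: CleanConfig | None = None,
    fields: Iterable[str] = ("novelty", "use"),
) -> set[str]:
    """Forms whose terms occur in the record's cleaned token stream(s).

    The common-word filter is bypassed for matching so that lexicon terms
    cannot silently remove themselves; a patent can match several forms.
    """
    if cfg is None:
        cfg = CleanConfig()
    match_cfg = CleanConfig(
        stopwords=cfg.stopwords,
        common_words=set(),
        lemmatizer_id=cfg.lemmatizer_id,
        min_token_length=cfg.min_token_length,
    )
    tokens: list[str] = []
    for f in fields:
        raw = record.novelty_text if f == "novelty" else record.use_text
        tokens.extend(clean_text(raw or "", match_cfg).tokens)
        tokens.append("\x00")  # field boundary: phrases cannot straddle fields
    hits: set[str] = set()
    for form, terms in lexicon.forms.items():
        for term in terms:
            if _contains_phrase(tokens, _clean_term(term, cfg)):
                hits.add(form)
                break
    return hits


@dataclass
class TrendSeries:
    """Per-form patent counts by year, with totals and cumulative curves."""

    yearly: dict[str, dict[int, int]]
    totals: dict[str, int]
    missing_year: dict[str, int] = field(default_factory=dict)

    def cumulative(self) -> dict[str, dict[int, int]]:
        out: dict[str, dict[int, int]] = {}
        for form, series in self.yearly.items():
            running = 0
            cum: dict[int, int] = {}
            for year in sorted(series):
                running += series[year]
                cum[year] = running
            out[form] = cum
        return out

    def to_frame(self, cumulative: bool = False) -> pd.DataFrame:
        source = self.cumulative() if cumulative else self.yearly
        rows = [
            {"form": form, "year": year, "count": source[form][year]}
            for form in sorted(source)
            for year in sorted(source[form])
        ]
        return pd.DataFrame(rows, columns=["form", "year", "count"])

    def totals_frame(self) -> pd.DataFrame:
        rows = [
            {"form": form, "total": self.totals[form], "missing_year": self.missing_year.get(form, 0)}
            for form in sorted(self.totals)
        ]
        return pd.DataFrame(rows, columns=["form", "total", "missing_year"])


def trend_series(
    corpus: Iterable[PatentRecord],
    lexicon: DosageFormLexicon | None = None,
    cfg: CleanConfig | None = None,
    fields: Iterable[str] = ("novelty", "use"),
) -> TrendSeries:
    """Count matching patents per form and per year.

    Records without a usable year still contribute to the per-form totals
    and are tracked separately; each patent counts at most once per form.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    if cfg is None:
        cfg = CleanConfig()
    fields = tuple(fields)
    yearly: dict[str, dict[int, int]] = {form: {} for form in lexicon.forms}
    totals: dict[str, int] = {form: 0 for form in lexicon.forms}
    missing: dict[str, int] = {form: 0 for form in lexicon.forms}
    n = 0
    for rec in corpus:
        n += 1
        for form in match_dosage_forms(rec, lexicon, cfg, fields):
            totals[form] += 1
            if rec.year is None:
                missing[form] += 1
            else:
                yearly[form][rec.year] = yearly[form].get(rec.year, 0) + 1
    if n == 0:
        raise ValueError("empty corpus")
    # drop forms that never matched from the yearly map but keep totals=0
    yearly = {form: series for form, series in yearly.items() if series}
    return TrendSeries(yearly=yearly, totals=totals, missing_year=missing)
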