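"""Synthetic patent corpora with planted structure.

Real Derwent-style patent corpora are proprietary, so every pipeline
stage is exercised on generated corpora whose ground truth is known by
construction.  The generator plants:

* **topics** — each patent belongs to one of ``n_topics`` groups; each
  group owns a disjoint vocabulary whose words are drawn with Zipf
  weights so the per-patent top-M keyword lists are stable and
  topic-discriminative;
* **background mixing** — each token is, with probability ``mixing``
  (the usual mixing parameter mu of planted-partition benchmarks), drawn
  from a shared background vocabulary instead of the topic vocabulary;
* **surface noise** — fields are rendered as sentence-cased prose with
  stop words injected at a fixed rate, so the cleaning pipeline does
  real work on synthetic input;
* **dosage-form terms** — per-form inclusion probabilities inject real
  form words (tablet, gel, ...) into the *Use* field for trend mining;
* **years** — uniform over a configurable range.

The generator records everything it emits (topic labels, per-field token
counts, planted forms), which downstream tests use as exact oracles.
Identical seeds give byte-identical corpora.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .corpus import PatentRecord
from .preprocess import CleanConfig, clean_text

__all__ = [
    "GeneratorConfig",
    "PlantedTruth",
    "generate_corpus",
    "evaluate_recovery",
    "make_vocabulary",
]

_SYLLABLES = [
    a + b
    for a in "bdfgklmnprstvz"
    for b in "aeiou"
]

_NOISE_STOPWORDS = ["the", "of", "and", "in", "is", "with", "for", "by", "to", "that"]


@dataclass
class GeneratorConfig:
    """Study conditions for a planted-topic corpus.

    ``mixing`` is the probability that a content token comes from the
    background vocabulary rather than the patent's topic vocabulary;
    0 gives perfectly separated topics (inter-topic similarity exactly 1),
    values near 1 destroy the planted structure.
    """

    n_patents: int = 300
    n_topics: int = 5
    topic_vocab_size: int = 50
    background_vocab_size: int = 100
    mixing: float = 0.2
    tokens_per_field: int = 80
    year_range: tuple[int, int] = (2000, 2020)
    form_term_rates: Mapping[str, float] = field(
        default_factory=lambda: {"tablet": 0.15, "solution": 0.15, "powder": 0.10, "gel": 0.08}
    )
    seed: int = 0
    zipf_exponent: float = 1.2
    stopword_noise_rate: float = 0.2

    def validate(self) -> None:
        if self.n_patents < 0 or self.n_topics < 1:
            raise ValueError("n_patents must be >= 0 and n_topics >= 1")
        if not (0.0 <= self.mixing <= 1.0):
            raise ValueError(f"mixing must be in [0, 1], got {self.mixing}")
        for form, p in self.form_term_rates.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"form rate for {form!r} must be in [0, 1], got {p}")
        if self.stopword_noise_rate < 0 or self.stopword_noise_rate >= 1:
            raise ValueError("stopword_noise_rate must be in [0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth recorded while generating: the oracle for recovery
    and bookkeeping tests."""

    topics: dict[str, int]
    emitted: dict[str, dict[str, Counter]]  # pid -> field -> token counts
    forms: dict[str, set[str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"patent_id": pid, "topic": t} for pid, t in sorted(self.topics.items())]
        return pd.DataFrame(rows, columns=["patent_id", "topic"])


def make_vocabulary(size: int, cfg: CleanConfig | None = None, reserved: set[str] | None = None) -> list[str]:
    """Deterministic pronounceable pseudo-words that survive the cleaning
    pipeline unchanged (no stop words, fixed under lemmatization, and
    pairwise distinct after cleaning)."""
    if cfg is None:
        cfg = CleanConfig()
    reserved = set(reserved or ())
    out: list[str] = []
    for combo in itertools.product(_SYLLABLES, repeat=3):
        word = "".join(combo)
        if word in reserved:
            continue
        cleaned = clean_text(word, cfg).tokens
        if cleaned != [word]:
            continue  # altered by cleaning: would break bookkeeping
        reserved.add(word)
        out.append(word)
        if len(out) == size:
            return out
    raise ValueError(f"vocabulary space exhausted before reaching {size} words")


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def _render(tokens: list[str], rng: np.random.Generator, noise_rate: float) -> str:
    """Space-joined prose with injected stop words, sentence casing and
    terminal periods — surface noise for the cleaning stage to remove."""
    noisy: list[str] = []
    for tok in tokens:
        if rng.random() < noise_rate:
            noisy.append(_NOISE_STOPWORDS[rng.integers(len(_NOISE_STOPWORDS))])
        noisy.append(tok)
    if not noisy:
        return ""
    sentences = []
    start = 0
    while start < len(noisy):
        length = int(rng.integers(8, 15))
        chunk = noisy[start : start + length]
        sentences.append(chunk[0].capitalize() + (" " + " ".join(chunk[1:]) if len(chunk) > 1 else "") + ".")
        start += length
    return " ".join(sentences)


def generate_corpus(cfg: GeneratorConfig | None = None) -> tuple[list[PatentRecord], PlantedTruth]:
    """Generate a planted-topic corpus and its ground truth.

    Topic vocabularies are pairwise disjoint and disjoint from the
    background vocabulary.  Each patent draws a topic uniformly; both
    text fields then draw ``tokens_per_field`` tokens i.i.d. — topic
    words with Zipf weights with probability ``1 - mixing``, uniform
    background words otherwise.  Deterministic given ``cfg.seed``.
    """
    if cfg is None:
        cfg = GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    clean_cfg = CleanConfig()

    form_words = sorted(cfg.form_term_rates)
    vocab_total = cfg.n_topics * cfg.topic_vocab_size + cfg.background_vocab_size
    words = make_vocabulary(vocab_total, clean_cfg, reserved=set(form_words))
    topic_vocabs = [
        words[t * cfg.topic_vocab_size : (t + 1) * cfg.topic_vocab_size]
        for t in range(cfg.n_topics)
    ]
    background = words[cfg.n_topics * cfg.topic_vocab_size :]
    zipf = _zipf_weights(cfg.topic_vocab_size, cfg.zipf_exponent)

    records: list[PatentRecord] = []
    topics: dict[str, int] = {}
    emitted: dict[str, dict[str, Counter]] = {}
    planted_forms: dict[str, set[str]] = {}

    width = max(4, len(str(max(cfg.n_patents - 1, 0))))
    for i in range(cfg.n_patents):
        pid = f"P{i:0{width}d}"
        topic = int(rng.integers(cfg.n_topics))
        topics[pid] = topic
        emitted[pid] = {}
        field_tokens: dict[str, list[str]] = {}
        for fname in ("novelty", "use"):
            k = cfg.tokens_per_field
            from_background = rng.random(k) < cfg.mixing
            n_bg = int(from_background.sum())
            toks = np.empty(k, dtype=object)
            if k - n_bg > 0:
                picks = rng.choice(cfg.topic_vocab_size, size=k - n_bg, p=zipf)
                toks[~from_background] = np.array(topic_vocabs[topic], dtype=object)[picks]
            if n_bg > 0 and cfg.background_vocab_size > 0:
                picks = rng.integers(cfg.background_vocab_size, size=n_bg)
                toks[from_background] = np.array(background, dtype=object)[picks]
            elif n_bg > 0:
                # no background vocabulary configured: fall back to topic draws
                picks = rng.choice(cfg.topic_vocab_size, size=n_bg, p=zipf)
                toks[from_background] = np.array(topic_vocabs[topic], dtype=object)[picks]
            field_tokens[fname] = list(toks)
        hit_forms: set[str] = set()
        for form in form_words:
            if rng.random() < cfg.form_term_rates[form]:
                pos = int(rng.integers(len(field_tokens["use"]) + 1))
                field_tokens["use"].insert(pos, form)
                hit_forms.add(form)
        planted_forms[pid] = hit_forms
        for fname in ("novelty", "use"):
            emitted[pid][fname] = Counter(field_tokens[fname])
        year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
        records.append(
            PatentRecord(
                patent_id=pid,
                year=year,
                novelty_text=_render(field_tokens["novelty"], rng, cfg.stopword_noise_rate),
                use_text=_render(field_tokens["use"], rng, cfg.stopword_noise_rate),
            )
        )
    truth = PlantedTruth(topics=topics, emitted=emitted, forms=planted_forms)
    return records, truth


def evaluate_recovery(partition, truth: PlantedTruth) -> dict[str, float]:
    """Agreement between a detected partition and the planted topics:
    normalized mutual information and adjusted Rand index (both 1 for
    identical partitions up to relabeling)."""
    membership = partition.membership if hasattr(partition, "membership") else dict(partition)
    if set(membership) != set(truth.topics):
        raise ValueError(
            f"node sets differ: partition has {len(membership)}, truth has {len(truth.topics)}"
        )
    order = sorted(membership)
    pred = [membership[pid] for pid in order]
    true = [truth.topics[pid] for pid in order]
    # clamp floating noise back into the scores' defined ranges
    nmi = min(1.0, max(0.0, float(normalized_mutual_info_score(true, pred))))
    ari = min(1.0, max(-1.0, float(adjusted_rand_score(true, pred))))
    return {"nmi": nmi, "ari": ari}
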