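"""Semantic-similarity sampling for annotation enrichment.

The loop that acquired extra notes for the second labeling round:

1. build one query per risk factor by concatenating that label's
   annotator rationales (or a definition/custom fallback when no
   rationale exists yet, e.g. a label with zero round-1 notes);
2. rank the unlabeled pool by cosine similarity between sentence
   embeddings of the query and each note;
3. take the top K (K in 10-50 by convention);
4. keep candidates matching label-specific evidence phrases
   ("has fever", "lost weight", ...);
5. iterate over the six labels; the union of batches goes to annotators.

The sentence encoder is a pluggable interface. The default is a
deterministic lexical encoder (tf-idf over the embedded batch, L2
normalized) so the whole loop is hermetic and reproducible; trained
sentence encoders (denoising-autoencoder or contrastive) can be slotted
in behind the same interface.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .datatypes import LABEL_DEFINITIONS, LABELS, AdjudicatedRecord, ClinicalNote, RiskFactorVector
from .errors import ConfigError, EncoderError, UndefinedRateError


@runtime_checkable
class SentenceEncoder(Protocol):
    """Maps a batch of texts to fixed-width vectors, deterministically."""

    description: str

    def embed(self, texts: list[str]) -> np.ndarray: ...


class LexicalEncoder:
    """Deterministic tf-idf embedding of a batch (unigrams, L2 rows).

    Corpus statistics (vocabulary, idf) are computed over the batch passed
    to :meth:`embed`, so embeddings are batch-relative but fully
    deterministic: the same batch always yields the same vectors.
    """

    description = "lexical tf-idf (unigram, l2-normalized, batch-relative idf)"

    def embed(self, texts: list[str]) -> np.ndarray:
        try:
            vec = TfidfVectorizer(lowercase=True, norm="l2")
            return np.asarray(vec.fit_transform(texts).todense(), dtype=np.float64)
        except Exception as exc:  # pragma: no cover - sklearn failure path
            raise EncoderError(f"lexical encoder failed on batch of {len(texts)}") from exc


@dataclass
class Query:
    label: str
    text: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ConfigError(f"unknown label {self.label!r}")
        if not self.text:
            raise ConfigError("query text must be non-empty")


# phrase filters mirroring the study's noisy-output cleanup
DEFAULT_INCLUDE_PATTERNS: dict[str, list[str]] = {
    "cancer": [r"cancer", r"malignan", r"oncolog", r"chemotherapy"],
    "weight": [r"lost\s+\d+", r"weight\s+loss", r"lost weight"],
    "fever": [r"has fever", r"fever", r"febrile"],
    "infection": [r"infection"],
    "bowel": [r"incontinen", r"bowel", r"bladder"],
    "abreflex": [r"reflex", r"muscle power", r"weakness"],
}


@dataclass
class SamplingConfig:
    k: int = 25
    include_patterns: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_INCLUDE_PATTERNS.items()}
    )
    exclude_patterns: dict[str, list[str]] = field(default_factory=dict)
    encoder_choice: str = "lexical"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigError("k must be non-negative")
        if not 10 <= self.k <= 50:
            warnings.warn(
                f"k={self.k} is outside the conventional 10-50 range", stacklevel=2
            )


@dataclass
class RankedCandidate:
    note_id: str
    similarity: float
    rank: int  # 1-based, non-increasing in similarity


def build_query(
    labeled: list[AdjudicatedRecord], label: str, fallback_text: str | None = None
) -> Query:
    """Concatenate the label's rationales in corpus order; else fall back.

    ``fallback_text`` defaults to the risk-factor definition.
    """
    if fallback_text is None:
        fallback_text = LABEL_DEFINITIONS[label]
    if not fallback_text:
        raise ConfigError("fallback_text must be non-empty")
    snippets = [
        snip for rec in labeled for lab, snip in rec.rationales if lab == label
    ]
    return Query(label=label, text=" ".join(snippets) if snippets else fallback_text)


def rank_pool(
    query: Query, pool: list[ClinicalNote], encoder: SentenceEncoder
) -> list[RankedCandidate]:
    """Rank the pool by cosine similarity to the query, descending.

    Query and pool are embedded in a single batch; vectors are unit
    normalized before the dot product (zero vectors stay zero). Ties are
    broken by note_id ascending.
    """
    if not pool:
        raise ConfigError("pool must be non-empty")
    vectors = encoder.embed([query.text] + [n.text for n in pool])
    vectors = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if vectors.shape[0] != len(pool) + 1:
        raise EncoderError(
            f"encoder returned {vectors.shape[0]} rows for batch of {len(pool) + 1}"
        )
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    unit = vectors / norms
    sims = unit[1:] @ unit[0]
    order = sorted(range(len(pool)), key=lambda i: (-sims[i], pool[i].note_id))
    return [
        RankedCandidate(note_id=pool[i].note_id, similarity=float(sims[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]


def select_top_k(ranked: list[RankedCandidate], k: int) -> list[RankedCandidate]:
    """First min(k, n) candidates, order preserved."""
    if k < 0:
        raise ConfigError("k must be non-negative")
    if k == 0:
        warnings.warn("select_top_k with k=0 returns an empty batch", stacklevel=2)
    return ranked[:k]


def _compile(patterns: list[str]) -> list[re.Pattern]:
    out = []
    for p in patterns:
        try:
            out.append(re.compile(p, re.IGNORECASE))
        except re.error as exc:
            raise ConfigError(f"invalid phrase pattern {p!r}: {exc}") from exc
    return out


def phrase_filter(
    candidates: list[RankedCandidate],
    notes_by_id: dict[str, ClinicalNote],
    include_patterns: list[str],
    exclude_patterns: list[str] | None = None,
) -> list[RankedCandidate]:
    """Keep candidates whose text matches >=1 include pattern (case-insensitive).

    An empty include list passes everything through; exclude patterns (if
    given) then drop matches. Rank order is preserved.
    """
    inc = _compile(include_patterns)
    exc = _compile(exclude_patterns or [])
    kept = []
    for cand in candidates:
        text = notes_by_id[cand.note_id].text
        if inc and not any(p.search(text) for p in inc):
            continue
        if exc and any(p.search(text) for p in exc):
            continue
        kept.append(cand)
    return kept


def sampling_round(
    labeled: list[AdjudicatedRecord],
    pool: list[ClinicalNote],
    encoder: SentenceEncoder,
    config: SamplingConfig,
) -> dict[str, list[ClinicalNote]]:
    """One enrichment round: per-label query -> rank -> top-K -> phrase filter.

    Notes already in the labeled set are excluded from the pool. Batches may
    overlap across labels; use :func:`dedup_union` for the deduplicated set
    handed to annotators.
    """
    labeled_ids = {rec.note.note_id for rec in labeled}
    eligible = [n for n in pool if n.note_id not in labeled_ids]
    if not eligible:
        raise ConfigError("pool contains no unlabeled notes")
    notes_by_id = {n.note_id: n for n in eligible}
    batches: dict[str, list[ClinicalNote]] = {}
    for label in LABELS:
        query = build_query(labeled, label)
        ranked = rank_pool(query, eligible, encoder)
        top = select_top_k(ranked, config.k)
        kept = phrase_filter(
            top,
            notes_by_id,
            config.include_patterns.get(label, []),
            config.exclude_patterns.get(label),
        )
        batches[label] = [notes_by_id[c.note_id] for c in kept]
    return batches


def dedup_union(batches: dict[str, list[ClinicalNote]]) -> list[ClinicalNote]:
    """Deduplicated union of per-label batches, label then rank order."""
    seen: set[str] = set()
    out: list[ClinicalNote] = []
    for label in LABELS:
        for note in batches.get(label, []):
            if note.note_id not in seen:
                seen.add(note.note_id)
                out.append(note)
    return out


@dataclass
class EnrichmentResult:
    rate: float  # fraction of batch notes with >=1 positive label
    n_positive: int
    n: int
    base_rate: float | None = None  # pool positive fraction, for comparison


def enrichment_rate(
    batch: list[ClinicalNote],
    hidden_gold: dict[str, RiskFactorVector],
    pool_ids: list[str] | None = None,
) -> EnrichmentResult:
    """Fraction of a sampled batch exhibiting >=1 risk factor.

    ``hidden_gold`` maps note_id to the held-out gold labels. If
    ``pool_ids`` is given, the pool's base positive rate is reported for
    comparison (enrichment means rate > base_rate).
    """
    if not batch:
        raise UndefinedRateError("enrichment rate of an empty batch is undefined")
    n_pos = sum(1 for n in batch if not hidden_gold[n.note_id].is_null)
    base = None
    if pool_ids is not None and pool_ids:
        base = sum(1 for i in pool_ids if not hidden_gold[i].is_null) / len(pool_ids)
    return EnrichmentResult(
        rate=n_pos / len(batch), n_positive=n_pos, n=len(batch), base_rate=base
    )
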