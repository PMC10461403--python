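"""Reproducible desk-scale experiments over synthetic corpora.

Each routine runs one complete study on generated data and returns the
quantities of interest. They are deliberately small (hundreds of notes, a
tiny backbone, scaled chunk boundaries) so a full run finishes in minutes
on one CPU; docs/methods.md records the problem sizes and what they do and
do not demonstrate. The acceptance checks and the `scripts/acceptance.py`
report both call these functions, so the numbers they state are always
recomputed by the same procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chunked_classifier import (
    AdaptationConfig,
    ChunkingConfig,
    ModelConfig,
    TrainConfig,
    build_model,
    domain_adapt,
)
from .datatypes import LABELS, AdjudicatedRecord
from .eval_harness import (
    TfidfLogisticBaseline,
    auroc,
    downsample_null,
    evaluate_model,
    iterative_stratified_kfold,
)
from .nn import BackboneConfig, TinyEncoder
from .sts_sampling import LexicalEncoder, SamplingConfig, dedup_union, sampling_round
from .synthetic_notes import (
    EvidencePositionPolicy,
    LengthDistribution,
    SyntheticCorpusSpec,
    generate_corpus,
    generate_unlabeled_pool,
    records_to_adjudicated,
)
from .tokenizer import WordTokenizer

#: uniform marginals and short notes: a clearly separable test-bed
SEPARABLE_MARGINALS = {lab: 0.12 for lab in LABELS}

#: evidence phrases built purely from background-vocabulary words, so the
#: signal lives in word combinations rather than distinctive tokens
WEAK_SNIPPET_BANK = {
    "cancer": ["chart reviewed oncology referral made today"],
    "weight": ["clothes loose appetite reduced since onset"],
    "fever": ["warm tonight sweating since last week"],
    "infection": ["wound region warm tender since incident"],
    "bowel": ["control issues since onset at home"],
    "abreflex": ["leg response reduced on exam today"],
}


def separable_spec(seed: int, n_notes: int = 300, **overrides) -> SyntheticCorpusSpec:
    kwargs = dict(
        n_notes=n_notes,
        null_fraction=0.5,
        label_marginals=dict(SEPARABLE_MARGINALS),
        length=LengthDistribution(
            mu=float(np.log(40)), sigma=0.5, min_tokens=10, max_tokens=120
        ),
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticCorpusSpec(**kwargs)


def _tiny_model(records, seed, chunking, epochs=12, learning_rate=1.5e-3,
                arch="chunked", extra_texts=()):
    tokenizer = WordTokenizer.build(
        [r.note.text for r in records] + list(extra_texts)
    )
    config = ModelConfig(
        backbone=BackboneConfig(
            vocab_size=tokenizer.vocab_size,
            max_len=chunking.max_tokens_per_chunk,
            seed=seed,
        ),
        chunking=chunking,
        seed=seed,
    )
    tc = TrainConfig(epochs=epochs, learning_rate=learning_rate, batch_size=8, seed=seed)
    return build_model(config, tokenizer, tc, arch=arch), tokenizer


def _single_split(records, seed):
    (fa,) = iterative_stratified_kfold(records, k=2, repeats=1, seed=seed)
    by_id = {r.note.note_id: r for r in records}
    train = [by_id[nid] for nid, f in fa.assignment.items() if f == 0]
    test = [by_id[nid] for nid, f in fa.assignment.items() if f == 1]
    return train, test


def _macro(model, test: list[AdjudicatedRecord]) -> float:
    scores = model.score([r.note for r in test])
    y = np.stack([r.labels.as_array() for r in test])
    vals = [auroc(scores[:, j], y[:, j]) for j in range(len(LABELS))]
    return float(np.mean([v for v in vals if v is not None]))


@dataclass
class EndToEndResult:
    macro_auroc: float
    macro_sd: float
    n_notes: int
    n_sampled: int
    enrichment_rate: float
    pool_base_rate: float


def end_to_end(seed: int, n_notes: int = 300, n_pool: int = 400) -> EndToEndResult:
    """Generate -> STS-sample -> split -> downsample -> train -> evaluate.

    The corpus is separable (evidence snippets present verbatim) with a
    moderately imbalanced null class so the downsampling step is active.
    """
    spec = separable_spec(seed, n_notes=n_notes, null_fraction=0.7)
    records = records_to_adjudicated(generate_corpus(spec))
    pool, gold = generate_unlabeled_pool(spec, n_pool)

    batches = sampling_round(
        records, pool, LexicalEncoder(), SamplingConfig(k=25, seed=seed)
    )
    union = dedup_union(batches)
    pool_ids = [n.note_id for n in pool]
    base = sum(1 for i in pool_ids if not gold[i].is_null) / len(pool_ids)
    enr = (
        sum(1 for n in union if not gold[n.note_id].is_null) / len(union)
        if union
        else 0.0
    )

    chunking = ChunkingConfig(max_tokens_per_chunk=64, max_chunks=3)
    model, _ = _tiny_model(records, seed, chunking)
    folds = iterative_stratified_kfold(records, k=2, repeats=1, seed=seed)
    report = evaluate_model(
        model, records, folds, downsample=True, downsample_seed=seed,
        model_name="chunked-multitask",
    )
    mean, sd = report.macro_mean_sd()
    return EndToEndResult(
        macro_auroc=mean, macro_sd=sd, n_notes=n_notes,
        n_sampled=len(union), enrichment_rate=enr, pool_base_rate=base,
    )


def longnote_advantage(
    seeds: list[int], n_notes: int = 200, boundary: int = 30
) -> dict[str, float]:
    """Chunked vs truncated macro-AUROC when evidence hides past chunk 1.

    For 80% of positive notes all evidence is placed after ``boundary``
    content tokens — exactly one chunk at the scaled 32-token chunk size —
    so a first-chunk-only model cannot see it.
    """
    chunked, truncated = [], []
    chunking = ChunkingConfig(max_tokens_per_chunk=boundary + 2, max_chunks=4)
    for seed in seeds:
        spec = separable_spec(
            seed,
            n_notes=n_notes,
            length=LengthDistribution(
                mu=float(np.log(45)), sigma=0.4, min_tokens=10, max_tokens=110
            ),
            evidence_position_policy=EvidencePositionPolicy(
                mode="force_tail", tail_fraction=0.8, boundary=boundary
            ),
        )
        records = records_to_adjudicated(generate_corpus(spec))
        train, test = _single_split(records, seed)
        for arch, sink in (("chunked", chunked), ("truncated", truncated)):
            model, _ = _tiny_model(records, seed, chunking, epochs=10, arch=arch)
            model.fit(train)
            sink.append(_macro(model, test))
    return {
        "chunked": float(np.mean(chunked)),
        "truncated": float(np.mean(truncated)),
        "delta": float(np.mean(chunked) - np.mean(truncated)),
    }


def downsampling_effect(seeds: list[int], n_notes: int = 400) -> dict[str, float]:
    """Macro-AUROC with vs without null-class downsampling of the train split.

    Conditions: weak combination-only signal, ~88% null class, tiny chunked
    multitask model, one stratified split per seed.
    """
    with_ds, without_ds = [], []
    chunking = ChunkingConfig(max_tokens_per_chunk=64, max_chunks=2)
    for seed in seeds:
        spec = SyntheticCorpusSpec(
            n_notes=n_notes,
            null_fraction=0.88,
            label_marginals={
                lab: p
                for lab, p in zip(LABELS, [0.025, 0.02, 0.02, 0.02, 0.02, 0.05])
            },
            snippet_bank={k: list(v) for k, v in WEAK_SNIPPET_BANK.items()},
            confuser_rate=0.0,
            length=LengthDistribution(
                mu=float(np.log(35)), sigma=0.4, min_tokens=10, max_tokens=90
            ),
            seed=1000 + seed,
        )
        records = records_to_adjudicated(generate_corpus(spec))
        train, test = _single_split(records, seed)
        for downsample, sink in ((False, without_ds), (True, with_ds)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train_set = downsample_null(train, seed=seed) if downsample else train
            model, _ = _tiny_model(records, seed, chunking, epochs=6)
            model.fit(train_set)
            sink.append(_macro(model, test))
    return {
        "with_downsampling": float(np.mean(with_ds)),
        "without_downsampling": float(np.mean(without_ds)),
        "delta": float(np.mean(with_ds) - np.mean(without_ds)),
    }


def mlm_adaptation_effect(
    seeds: list[int], n_notes: int = 240, n_pool: int = 250
) -> dict[str, float]:
    """Fine-tuning from an MLM-adapted backbone vs from scratch.

    Gentle continued pretraining (3 epochs at lr 5e-4) on an unlabeled pool,
    followed by an epoch-limited fine-tune (4 epochs) on a separable corpus.
    """
    adapted_scores, scratch_scores = [], []
    chunking = ChunkingConfig(max_tokens_per_chunk=64, max_chunks=3)
    for seed in seeds:
        spec = separable_spec(seed, n_notes=n_notes)
        records = records_to_adjudicated(generate_corpus(spec))
        pool, _ = generate_unlabeled_pool(spec, n_pool)
        train = records[: int(n_notes * 2 / 3)]
        test = records[int(n_notes * 2 / 3) :]
        pool_texts = [n.text for n in pool]

        scratch, tokenizer = _tiny_model(
            records, seed, chunking, epochs=4, learning_rate=1e-3,
            extra_texts=pool_texts,
        )
        backbone = TinyEncoder(
            BackboneConfig(vocab_size=tokenizer.vocab_size, max_len=64, seed=seed)
        )
        backbone, _ = domain_adapt(
            backbone, pool, tokenizer,
            AdaptationConfig(objective="mlm", epochs=3, learning_rate=5e-4, seed=seed),
            chunking,
        )
        adapted, _ = _tiny_model(
            records, seed, chunking, epochs=4, learning_rate=1e-3,
            extra_texts=pool_texts,
        )
        adapted.set_backbone(backbone)
        scratch.fit(train)
        adapted.fit(train)
        scratch_scores.append(_macro(scratch, test))
        adapted_scores.append(_macro(adapted, test))
    return {
        "adapted": float(np.mean(adapted_scores)),
        "scratch": float(np.mean(scratch_scores)),
        "delta": float(np.mean(adapted_scores) - np.mean(scratch_scores)),
    }


def baseline_macro(seeds: list[int], n_notes: int = 500) -> float:
    """Cross-validated tf-idf + logistic macro-AUROC on separable corpora."""
    macros = []
    for seed in seeds:
        records = records_to_adjudicated(generate_corpus(separable_spec(seed, n_notes)))
        folds = iterative_stratified_kfold(records, k=2, repeats=1, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evaluate_model(
                TfidfLogisticBaseline(seed=seed), records, folds, downsample=True
            )
        macros.append(report.macro_mean_sd()[0])
    return float(np.mean(macros))
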