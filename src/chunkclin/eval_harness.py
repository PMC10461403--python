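"""Experimental scaffolding: stratified CV, downsampling, AUROC reporting.

The study design this harness reproduces: repeated 2-fold cross-validation
(2 repeats = 4 runs) with multi-label *iterative stratification*, optional
downsampling of the null class on the training split only, per-label and
macro AUROC with across-run standard deviations, and a tf-idf +
logistic-regression multi-output baseline.

Iterative stratification is the greedy algorithm for multi-label data:
process the label with the fewest remaining positive examples first and
assign each of its examples to the fold with the greatest remaining demand
for that label, breaking ties by overall remaining fold capacity and then
seeded-randomly. Fold capacities are fixed to floor/ceil(n/k) so fold sizes
differ by at most one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .datatypes import LABELS, AdjudicatedRecord, ClinicalNote
from .errors import ConfigError, DegenerateSplitError


@dataclass
class FoldAssignment:
    """One repeat's assignment of every note to a fold in 0..k-1."""

    assignment: dict[str, int]
    k: int
    repeat: int
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [nid for nid, f in self.assignment.items() if f == fold]


def _stratify_once(
    records: list[AdjudicatedRecord], k: int, rng: np.random.Generator
) -> dict[str, int]:
    n = len(records)
    capacity = np.full(k, n // k, dtype=np.int64)
    capacity[: n % k] += 1

    ids = [r.note.note_id for r in records]
    label_sets = {r.note.note_id: set(r.labels.positive_labels()) for r in records}
    unassigned = set(ids)
    # desired remaining per-fold count of each label
    desire = {
        lab: np.full(k, sum(1 for r in records if getattr(r.labels, lab)) / k)
        for lab in LABELS
    }
    assignment: dict[str, int] = {}

    def assign(note_id: str, fold: int) -> None:
        assignment[note_id] = fold
        unassigned.discard(note_id)
        capacity[fold] -= 1
        for lab in label_sets[note_id]:
            desire[lab][fold] -= 1.0

    while True:
        remaining_counts = {
            lab: sum(1 for nid in unassigned if lab in label_sets[nid]) for lab in LABELS
        }
        positive_labels = [lab for lab, c in remaining_counts.items() if c > 0]
        if not positive_labels:
            break
        # rarest label first; ties by canonical label order
        lab = min(positive_labels, key=lambda l: (remaining_counts[l], LABELS.index(l)))
        members = [nid for nid in ids if nid in unassigned and lab in label_sets[nid]]
        order = rng.permutation(len(members))
        for idx in order:
            nid = members[idx]
            open_folds = [f for f in range(k) if capacity[f] > 0]
            if not open_folds:  # pragma: no cover - capacities sum to n
                raise ConfigError("fold capacities exhausted")
            best_desire = max(desire[lab][f] for f in open_folds)
            cands = [f for f in open_folds if desire[lab][f] == best_desire]
            if len(cands) > 1:
                best_cap = max(capacity[f] for f in cands)
                cands = [f for f in cands if capacity[f] == best_cap]
            fold = int(cands[int(rng.integers(len(cands)))]) if len(cands) > 1 else cands[0]
            assign(nid, fold)

    # null-class (and any leftover) notes: fill by remaining capacity
    leftovers = [nid for nid in ids if nid in unassigned]
    order = rng.permutation(len(leftovers))
    for idx in order:
        nid = leftovers[idx]
        open_folds = [f for f in range(k) if capacity[f] > 0]
        best_cap = max(capacity[f] for f in open_folds)
        cands = [f for f in open_folds if capacity[f] == best_cap]
        fold = int(cands[int(rng.integers(len(cands)))]) if len(cands) > 1 else cands[0]
        assign(nid, fold)
    return assignment


def iterative_stratified_kfold(
    records: list[AdjudicatedRecord], k: int = 2, repeats: int = 1, seed: int = 0
) -> list[FoldAssignment]:
    """Multi-label stratified k-fold assignments, one per repeat."""
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > len(records):
        raise ConfigError(f"k={k} exceeds the number of records ({len(records)})")
    out = []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        out.append(
            FoldAssignment(
                assignment=_stratify_once(records, k, rng), k=k, repeat=rep, seed=seed
            )
        )
    return out


def downsample_null(
    train_records: list[AdjudicatedRecord], seed: int = 0
) -> list[AdjudicatedRecord]:
    """Downsample null-class training notes to match the any-positive count.

    All positive notes are retained (identity, not resampling); null notes
    are sampled without replacement, seeded, and the combined order is
    shuffled with the same seed. The test split is never passed here.
    """
    positives = [r for r in train_records if not r.labels.is_null]
    nulls = [r for r in train_records if r.labels.is_null]
    if not positives:
        raise DegenerateSplitError("training split has no positive notes")
    rng = np.random.default_rng(seed)
    if len(nulls) <= len(positives):
        if len(nulls) < len(positives):
            warnings.warn(
                f"only {len(nulls)} null notes for {len(positives)} positives; "
                "keeping all nulls",
                stacklevel=2,
            )
        chosen = nulls
    else:
        idx = rng.choice(len(nulls), size=len(positives), replace=False)
        chosen = [nulls[int(i)] for i in idx]
    combined = positives + chosen
    rng.shuffle(combined)
    return combined


def auroc(scores: Iterable[float], labels: Iterable[int]) -> float | None:
    """Rank-based (Mann-Whitney, midrank ties) AUROC; None if single-class."""
    y = np.asarray(list(labels), dtype=np.int64)
    s = np.asarray(list(scores), dtype=np.float64)
    if y.shape != s.shape:
        raise ConfigError("scores and labels must have the same length")
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, s))


class MultiLabelModel(Protocol):
    """fit on adjudicated records; score notes to an (n, 6) array."""

    def fit(self, train: list[AdjudicatedRecord]) -> "MultiLabelModel": ...

    def score(self, notes: list[ClinicalNote]) -> np.ndarray: ...


@dataclass
class RunResult:
    repeat: int
    test_fold: int
    per_label: dict[str, float | None]

    @property
    def macro(self) -> float | None:
        defined = [v for v in self.per_label.values() if v is not None]
        return float(np.mean(defined)) if defined else None


@dataclass
class EvalReport:
    """AUROC per run plus mean/SD aggregates across runs (ddof=1)."""

    runs: list[RunResult]
    model_name: str = "model"
    downsampled: bool = False
    seed: int = 0
    undefined_labels: list[tuple[int, int, str]] = field(default_factory=list)

    def _agg(self, values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=np.float64)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        return float(np.mean(arr)), sd

    def label_mean_sd(self, label: str) -> tuple[float, float] | None:
        vals = [r.per_label[label] for r in self.runs if r.per_label[label] is not None]
        return self._agg(vals) if vals else None

    def macro_mean_sd(self) -> tuple[float, float]:
        vals = [r.macro for r in self.runs if r.macro is not None]
        if not vals:
            raise ConfigError("no run produced a defined macro-AUROC")
        return self._agg(vals)

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.runs:
            for lab in LABELS:
                rows.append(
                    {
                        "repeat": r.repeat,
                        "test_fold": r.test_fold,
                        "label": lab,
                        "auroc": r.per_label[lab],
                    }
                )
            rows.append(
                {
                    "repeat": r.repeat,
                    "test_fold": r.test_fold,
                    "label": "macro",
                    "auroc": r.macro,
                }
            )
        return pd.DataFrame(rows)


def evaluate_model(
    model: MultiLabelModel,
    records: list[AdjudicatedRecord],
    folds: list[FoldAssignment],
    downsample: bool = False,
    downsample_seed: int = 0,
    model_name: str = "model",
) -> EvalReport:
    """Cross-validated evaluation: each fold serves once as the test split.

    Downsampling, when enabled, is applied to the *training* split only;
    the test split is scored untouched. Per-label AUROCs undefined in a run
    (single-class test labels) are recorded and excluded from that run's
    macro average.
    """
    by_id = {r.note.note_id: r for r in records}
    report = EvalReport(
        runs=[], model_name=model_name, downsampled=downsample,
        seed=folds[0].seed if folds else 0,
    )
    for fa in folds:
        for test_fold in range(fa.k):
            test = [by_id[nid] for nid in fa.fold_ids(test_fold)]
            train = [
                by_id[nid] for nid, f in fa.assignment.items() if f != test_fold
            ]
            if downsample:
                train = downsample_null(train, seed=downsample_seed + fa.repeat)
            model.fit(train)
            scores = np.asarray(model.score([r.note for r in test]), dtype=np.float64)
            y = np.stack([r.labels.as_array() for r in test])
            per_label: dict[str, float | None] = {}
            for j, lab in enumerate(LABELS):
                value = auroc(scores[:, j], y[:, j])
                per_label[lab] = value
                if value is None:
                    report.undefined_labels.append((fa.repeat, test_fold, lab))
            report.runs.append(
                RunResult(repeat=fa.repeat, test_fold=test_fold, per_label=per_label)
            )
    return report


class TfidfLogisticBaseline:
    """tf-idf + one independent logistic classifier per label.

    Unigram tf-idf (sublinear tf off, L2 normalization) on the training
    vocabulary; per-label L2-regularized logistic regression at default
    strength. Labels with a single class in the training split get constant
    prior scores and are flagged in ``constant_labels``.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.constant_labels: list[str] = []

    def fit(self, train: list[AdjudicatedRecord]) -> "TfidfLogisticBaseline":
        self._vectorizer = TfidfVectorizer(lowercase=True, sublinear_tf=False, norm="l2")
        X = self._vectorizer.fit_transform([r.note.text for r in train])
        Y = np.stack([r.labels.as_array() for r in train])
        self._models: list[LogisticRegression | float] = []
        self.constant_labels = []
        for j, lab in enumerate(LABELS):
            y = Y[:, j]
            if len(np.unique(y)) < 2:
                self._models.append(float(y.mean()))
                self.constant_labels.append(lab)
            else:
                clf = LogisticRegression(max_iter=2000, random_state=self.seed)
                clf.fit(X, y)
                self._models.append(clf)
        return self

    def score(self, notes: list[ClinicalNote]) -> np.ndarray:
        X = self._vectorizer.transform([n.text for n in notes])
        cols = []
        for m in self._models:
            if isinstance(m, float):
                cols.append(np.full(X.shape[0], m))
            else:
                cols.append(m.predict_proba(X)[:, 1])
        return np.stack(cols, axis=1)


def baseline_fit_predict(
    train: list[AdjudicatedRecord], test: list[ClinicalNote], seed: int = 0
) -> np.ndarray:
    """Fit the tf-idf + logistic baseline on train, return (n, 6) test scores."""
    model = TfidfLogisticBaseline(seed=seed).fit(train)
    return model.score(test)
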