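"""Synthetic clinical-note corpora with the statistical shape of the study data.

The generator emulates the documented structure of the annotated corpus:

* six binary risk-factor labels at the study's marginal prevalences
  (defaults: cancer 53, weight 32, fever 17, infection 9, bowel 9,
  abreflex 236 out of 2749 notes; ~87.4% of notes are the null class);
* note lengths (whitespace tokens) spanning 7-1400 with roughly 8% of
  notes longer than 512 tokens (clipped lognormal);
* positive labels witnessed by evidence snippets ("rationales") injected
  at recorded character offsets, with a policy controlling whether the
  evidence may be forced into the tail of long notes (past a chunk
  boundary), which is what makes truncated-input classifiers fail;
* confuser snippets drawn from the study's exclusion criteria (HIV,
  urinary symptoms other than incontinence, shingles, nocturnal enuresis,
  degenerative disease, pasted imaging results, resolved back pain, well
  child visits) that never flip a label;
* a patient/site hierarchy (default 22 sites, ~1.4 notes per patient) so
  multilevel summaries are meaningful.

Tokens here are whitespace-delimited words; the classifier re-tokenizes
with its own tokenizer. Same spec + same seed gives a byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import LABELS, ClinicalNote, RiskFactorVector
from .errors import SpecError

# Table-style defaults: per-label positive note counts out of 2749.
DEFAULT_LABEL_COUNTS = {
    "cancer": 53,
    "weight": 32,
    "fever": 17,
    "infection": 9,
    "bowel": 9,
    "abreflex": 236,
}
DEFAULT_N_NOTES = 2749
DEFAULT_NULL_FRACTION = 2402 / 2749

DEFAULT_SNIPPET_BANK: dict[str, list[str]] = {
    "cancer": [
        "history of metastatic breast cancer",
        "previously treated for prostate cancer",
        "known malignancy followed by oncology",
        "cancer survivor in remission after chemotherapy",
    ],
    "weight": [
        "unintentional weight loss of ten pounds",
        "lost 15 lbs without trying",
        "unexplained weight loss over two months",
        "marked weight loss clothes fitting loose",
    ],
    "fever": [
        "has fever and chills tonight",
        "febrile with temperature 38.9 this morning",
        "reports fever of 101 for three days",
        "low grade fever with night sweats",
    ],
    "infection": [
        "recent urinary tract infection treated with antibiotics",
        "recovering from recent skin infection",
        "recent infection requiring iv antibiotics",
        "post operative wound infection last month",
    ],
    "bowel": [
        "new loss of bowel control",
        "bladder incontinence related to a nerve issue",
        "cannot control bladder since yesterday",
        "fecal incontinence with saddle anesthesia",
    ],
    "abreflex": [
        "absent ankle jerk reflex on exam",
        "abnormal reflexes with weakness in both legs",
        "diminished patellar reflex on the left",
        "loss of muscle power in the legs",
    ],
}

DEFAULT_CONFUSER_BANK: list[str] = [
    "hiv viral load stable on therapy",
    "urinary frequency without any incontinence",
    "shingles rash in a lumbar dermatome",
    "childhood nocturnal enuresis reported",
    "degenerative disc disease with osteoarthritis noted",
    "imaging results copied into the chart",
    "previous back pain now fully resolved",
    "well child visit routine growth check",
]

_BACKGROUND_VOCAB = (
    "patient presents with lower back pain today denies numbness tingling "
    "radiation down leg exam unremarkable gait normal range of motion intact "
    "advised stretching heat ice rest ibuprofen acetaminophen prn follow up "
    "in two weeks discussed posture ergonomics work duties sleep hygiene "
    "vitals stable blood pressure normal pulse regular respiratory clear "
    "abdomen soft nontender no distress alert oriented mood appropriate "
    "reviewed medications refilled prescription physiotherapy referral made "
    "stretching exercises demonstrated core strengthening encouraged walking "
    "daily activity modification discussed return if symptoms worsen chart "
    "updated consent obtained assessment plan documented soft tissue strain "
    "muscular tenderness paraspinal region mild moderate improving gradually "
    "since onset last week lifting incident at home no trauma reported"
).split()


@dataclass
class LengthDistribution:
    """Clipped lognormal over whitespace-token note lengths.

    Defaults put the median near 126 tokens and ~8% of mass above 512,
    clipped to [7, 1400].
    """

    mu: float = 4.833
    sigma: float = 1.0
    min_tokens: int = 7
    max_tokens: int = 1400

    def sample(self, rng: np.random.Generator) -> int:
        x = int(round(float(np.exp(rng.normal(self.mu, self.sigma)))))
        return int(np.clip(x, self.min_tokens, self.max_tokens))


@dataclass
class EvidencePositionPolicy:
    """Where evidence snippets may land inside a positive note.

    mode="anywhere": uniform over the note.
    mode="force_tail": for ``tail_fraction`` of positive notes, the note is
    long enough and *all* evidence is placed after ``boundary`` tokens —
    invisible to a classifier that truncates at the first chunk.
    """

    mode: str = "anywhere"
    tail_fraction: float = 0.0
    boundary: int = 512

    def __post_init__(self) -> None:
        if self.mode not in ("anywhere", "force_tail"):
            raise SpecError(f"unknown evidence position mode {self.mode!r}")
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise SpecError("tail_fraction must be in [0, 1]")


@dataclass
class SyntheticCorpusSpec:
    n_notes: int = DEFAULT_N_NOTES
    label_marginals: dict[str, float] = field(
        default_factory=lambda: {
            lab: DEFAULT_LABEL_COUNTS[lab] / DEFAULT_N_NOTES for lab in LABELS
        }
    )
    null_fraction: float = DEFAULT_NULL_FRACTION
    length: LengthDistribution = field(default_factory=LengthDistribution)
    evidence_position_policy: EvidencePositionPolicy = field(
        default_factory=EvidencePositionPolicy
    )
    snippet_bank: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SNIPPET_BANK.items()}
    )
    confuser_bank: list[str] = field(default_factory=lambda: list(DEFAULT_CONFUSER_BANK))
    confuser_rate: float = 0.15
    n_sites: int = 22
    mean_notes_per_patient: float = 2749 / 1943
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes <= 0:
            raise SpecError("n_notes must be positive")
        if not 0.0 <= self.null_fraction <= 1.0:
            raise SpecError("null_fraction must be a probability")
        for lab in LABELS:
            p = self.label_marginals.get(lab, 0.0)
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"marginal for {lab!r} must be a probability")
        if self.length.min_tokens < 7:
            raise SpecError("minimum note length must be >= 7 tokens")
        longest = max(
            (len(s.split()) for bank in self.snippet_bank.values() for s in bank),
            default=0,
        )
        longest = max(longest, max((len(s.split()) for s in self.confuser_bank), default=0))
        if longest > self.length.min_tokens:
            raise SpecError(
                f"longest snippet has {longest} tokens, exceeding the minimum "
                f"note length {self.length.min_tokens}"
            )

    def conditional_label_probs(self) -> dict[str, float]:
        """Per-label probabilities *within the positive class*.

        Labels are drawn independently conditioned on "note is positive"
        (all-zero draws are rejected).  A fixed-point calibration scales the
        conditional probabilities so the unconditional marginals equal
        ``label_marginals`` despite the rejection step.
        """
        pos_frac = 1.0 - self.null_fraction
        if pos_frac <= 0.0:
            return {lab: 0.0 for lab in LABELS}
        q = {lab: min(1.0, self.label_marginals.get(lab, 0.0) / pos_frac) for lab in LABELS}
        for _ in range(50):
            p_any = 1.0 - float(np.prod([1.0 - q[lab] for lab in LABELS]))
            if p_any <= 0.0:
                break
            q = {
                lab: min(1.0, self.label_marginals.get(lab, 0.0) * p_any / pos_frac)
                for lab in LABELS
            }
        return q


@dataclass
class GoldRecord:
    """A synthetic note with its gold labels and evidence-span provenance.

    ``rationale_spans`` holds (label, start, end) character offsets; the
    slice ``note.text[start:end]`` is the injected evidence snippet.
    """

    note: ClinicalNote
    labels: RiskFactorVector
    rationale_spans: list[tuple[str, int, int]] = field(default_factory=list)

    def rationales(self) -> list[tuple[str, str]]:
        return [
            (lab, self.note.text[start:end]) for lab, start, end in self.rationale_spans
        ]


def _draw_labels(spec: SyntheticCorpusSpec, rng: np.random.Generator) -> RiskFactorVector:
    if rng.random() < spec.null_fraction:
        return RiskFactorVector()
    q = spec.conditional_label_probs()
    if all(q[lab] == 0.0 for lab in LABELS):
        return RiskFactorVector()
    for _ in range(10_000):
        draw = {lab: int(rng.random() < q[lab]) for lab in LABELS}
        if any(draw.values()):
            return RiskFactorVector(**draw)
    raise SpecError("could not draw a positive label combination")


def _place_snippets(
    n_tokens: int,
    snippets: list[tuple[str | None, list[str]]],
    lo: int,
    rng: np.random.Generator,
) -> list[tuple[str | None, int, int]]:
    """Choose non-overlapping word-index windows for snippets in [lo, n)."""
    placed: list[tuple[str | None, int, int]] = []  # (label, start_word, n_words)
    for label, words in snippets:
        w = len(words)
        for _ in range(50):
            if n_tokens - w < lo:
                start = max(0, n_tokens - w)
            else:
                start = int(rng.integers(lo, n_tokens - w + 1))
            if all(start + w <= s or start >= s + k for _, s, k in placed):
                placed.append((label, start, w))
                break
        else:
            # deterministic fallback: first free slot at or after lo
            for start in range(lo, n_tokens - w + 1):
                if all(start + w <= s or start >= s + k for _, s, k in placed):
                    placed.append((label, start, w))
                    break
    return placed


def _render_note(
    spec: SyntheticCorpusSpec,
    labels: RiskFactorVector,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[str, int, int]]]:
    n = spec.length.sample(rng)
    policy = spec.evidence_position_policy

    evidence: list[tuple[str | None, list[str]]] = []
    for lab in labels.positive_labels():
        snippet = spec.snippet_bank[lab][int(rng.integers(len(spec.snippet_bank[lab])))]
        evidence.append((lab, snippet.split()))

    lo = 0
    if evidence and policy.mode == "force_tail" and rng.random() < policy.tail_fraction:
        lo = policy.boundary
    if evidence:
        # guarantee room for every snippet (short notes with several labels)
        need = lo + sum(len(w) for _, w in evidence) + 2 * len(evidence) + 4
        n = max(n, need)

    words = [
        _BACKGROUND_VOCAB[int(i)] for i in rng.integers(len(_BACKGROUND_VOCAB), size=n)
    ]

    placed = _place_snippets(n, evidence, lo, rng)
    if len(placed) < len(evidence):
        # random placement fragmented the free space; lay the snippets out
        # sequentially from lo (the length guarantee makes this always fit)
        placed = []
        cursor = lo
        for lab, snippet_words_ in evidence:
            placed.append((lab, cursor, len(snippet_words_)))
            cursor += len(snippet_words_) + 1
        if cursor - 1 > n:  # pragma: no cover - sizing guarantee
            raise SpecError("could not place all evidence snippets")
    if rng.random() < spec.confuser_rate and spec.confuser_bank:
        confuser = spec.confuser_bank[int(rng.integers(len(spec.confuser_bank)))]
        cw = confuser.split()
        for _ in range(50):
            start = int(rng.integers(0, max(1, n - len(cw) + 1)))
            if all(start + len(cw) <= s or start >= s + k for _, s, k in placed):
                words[start : start + len(cw)] = cw
                placed.append((None, start, len(cw)))
                break

    snippet_words = {lab: words_ for lab, words_ in evidence}
    for lab, start, w in placed:
        if lab is not None:
            words[start : start + w] = snippet_words[lab]

    # character offsets: words joined by single spaces
    offsets = np.zeros(n + 1, dtype=np.int64)
    for i, word in enumerate(words):
        offsets[i + 1] = offsets[i] + len(word) + 1  # +1 for the joining space
    text = " ".join(words)
    spans = [
        (lab, int(offsets[start]), int(offsets[start + w] - 1))
        for lab, start, w in placed
        if lab is not None
    ]
    return text, spans


def _assign_hierarchy(
    spec: SyntheticCorpusSpec, n: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """(patient_id, site_id) per note; notes-per-patient ~ 1 + Poisson."""
    out: list[tuple[str, str]] = []
    patient = 0
    extra_mean = max(0.0, spec.mean_notes_per_patient - 1.0)
    while len(out) < n:
        site = int(rng.integers(spec.n_sites))
        k = 1 + int(rng.poisson(extra_mean))
        for _ in range(k):
            if len(out) >= n:
                break
            out.append((f"pt-{patient:05d}", f"site-{site:02d}"))
        patient += 1
    return out


def _generate(
    spec: SyntheticCorpusSpec, n: int, rng: np.random.Generator, id_prefix: str
) -> list[GoldRecord]:
    hierarchy = _assign_hierarchy(spec, n, rng)
    records = []
    for i in range(n):
        labels = _draw_labels(spec, rng)
        text, spans = _render_note(spec, labels, rng)
        patient_id, site_id = hierarchy[i]
        note = ClinicalNote(
            note_id=f"{id_prefix}-{i:05d}",
            patient_id=patient_id,
            site_id=site_id,
            text=text,
            note_type="encounter",
        )
        records.append(GoldRecord(note=note, labels=labels, rationale_spans=spans))
    return records


def generate_corpus(spec: SyntheticCorpusSpec) -> list[GoldRecord]:
    """Generate ``spec.n_notes`` labeled synthetic notes (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    return _generate(spec, spec.n_notes, rng, "note")


def generate_unlabeled_pool(
    spec: SyntheticCorpusSpec, n_pool: int
) -> tuple[list[ClinicalNote], dict[str, RiskFactorVector]]:
    """Generate an unlabeled pool emulating the study's unannotated note bank.

    Returns the notes and a held-out gold map (note_id -> labels) so that
    sampling enrichment can be evaluated. Pool note ids are disjoint from
    corpus ids by prefix.
    """
    if n_pool <= 0:
        raise SpecError("n_pool must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    records = _generate(spec, n_pool, rng, "pool")
    notes = [r.note for r in records]
    gold = {r.note.note_id: r.labels for r in records}
    return notes, gold


def records_to_adjudicated(records: list[GoldRecord]):
    """View gold records as adjudicated records (agreed, gold rationales)."""
    from .datatypes import AdjudicatedRecord

    return [
        AdjudicatedRecord(
            note=r.note, labels=r.labels, rationales=r.rationales(), provenance="agreed"
        )
        for r in records
    ]
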