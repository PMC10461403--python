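"""Deterministic synthetic corpora realizing the study's printed summary counts.

These builders construct *synthetic* stand-in corpora whose aggregate
counts equal the published summary tables of the annotated corpus
(2749 notes from 1943 patients across 22 sites), so the descriptive and
experimental-design machinery can be exercised against known arithmetic:

* :func:`table_count_corpus` — per-label note/patient/site counts equal to
  the multilevel summary table (e.g. cancer: 53 notes, 40 patients,
  12 sites; abreflex: 236 notes, 201 patients, 13 sites);
* :func:`single_label_count_corpus` — single-label corpus with the final
  per-label note counts (53/32/17/9/9/236), for stratification checks;
* :func:`positive_rate_batch` — a batch of notes with an exact hidden
  positive count, for annotation-round rate arithmetic (round 1:
  296/2487 positives; round 2: 51/262).

The note *texts* are placeholders; only identifiers and labels matter here.
"""

from __future__ import annotations

from .datatypes import LABELS, AdjudicatedRecord, ClinicalNote, RiskFactorVector

#: (notes, patients, sites) with >=1 positive note, per label.
MULTILEVEL_COUNTS: dict[str, tuple[int, int, int]] = {
    "cancer": (53, 40, 12),
    "weight": (32, 32, 12),
    "fever": (17, 17, 11),
    "infection": (9, 9, 5),
    "bowel": (9, 8, 7),
    "abreflex": (236, 201, 13),
}
N_NOTES, N_PATIENTS, N_SITES = 2749, 1943, 22

#: positives out of total annotated, per labeling round
ROUND1_POSITIVES, ROUND1_TOTAL = 296, 2487
ROUND2_POSITIVES, ROUND2_TOTAL = 51, 262

#: any-risk-factor vs null split of the final corpus
ANY_POSITIVE_NOTES, NULL_NOTES = 347, 2402


def _note(i: int, patient: str, site: str) -> ClinicalNote:
    return ClinicalNote(
        note_id=f"fx-{i:05d}", patient_id=patient, site_id=site,
        text=f"synthetic placeholder note {i}",
    )


def table_count_corpus() -> list[AdjudicatedRecord]:
    """Corpus whose multilevel summary reproduces the printed table exactly.

    Each label gets its own disjoint set of patients; a label's patients are
    spread round-robin over its first ``n_sites`` sites and its notes are
    spread over its patients (every patient at least one). Null-class
    patients fill the remaining patient and note totals across all sites.
    """
    records: list[AdjudicatedRecord] = []
    note_i = 0
    patient_i = 0
    for lab in LABELS:
        n_notes, n_patients, n_sites = MULTILEVEL_COUNTS[lab]
        labels = RiskFactorVector(**{lab: 1})
        patients = [f"pt-{patient_i + j:05d}" for j in range(n_patients)]
        patient_i += n_patients
        sites = [f"site-{j % n_sites:02d}" for j in range(n_patients)]
        # distribute notes: first patient absorbs the surplus
        per_patient = [1] * n_patients
        per_patient[0] += n_notes - n_patients
        for j, (pat, site) in enumerate(zip(patients, sites)):
            for _ in range(per_patient[j]):
                records.append(
                    AdjudicatedRecord(note=_note(note_i, pat, site), labels=labels)
                )
                note_i += 1
    n_null_patients = N_PATIENTS - patient_i
    n_null_notes = N_NOTES - note_i
    null = RiskFactorVector()
    extra = n_null_notes - n_null_patients  # null patients with a second note
    for j in range(n_null_patients):
        pat = f"pt-{patient_i + j:05d}"
        site = f"site-{j % N_SITES:02d}"
        for _ in range(2 if j < extra else 1):
            records.append(AdjudicatedRecord(note=_note(note_i, pat, site), labels=null))
            note_i += 1
    assert note_i == N_NOTES and patient_i + n_null_patients == N_PATIENTS
    return records


def single_label_count_corpus() -> list[AdjudicatedRecord]:
    """2749 notes with exact single-label positive counts; rest null class."""
    records: list[AdjudicatedRecord] = []
    i = 0
    for lab in LABELS:
        n_notes, _, _ = MULTILEVEL_COUNTS[lab]
        labels = RiskFactorVector(**{lab: 1})
        for _ in range(n_notes):
            records.append(
                AdjudicatedRecord(
                    note=_note(i, f"pt-{i:05d}", f"site-{i % N_SITES:02d}"),
                    labels=labels,
                )
            )
            i += 1
    while i < N_NOTES:
        records.append(
            AdjudicatedRecord(
                note=_note(i, f"pt-{i:05d}", f"site-{i % N_SITES:02d}"),
                labels=RiskFactorVector(),
            )
        )
        i += 1
    return records


def any_positive_split_corpus() -> list[AdjudicatedRecord]:
    """2749 notes: 347 with >=1 risk factor, 2402 null class.

    Label totals still equal the final per-label counts (356 label
    assignments): the nine bowel labels ride on the first nine abreflex
    notes, giving 347 distinct positive notes.
    """
    records: list[AdjudicatedRecord] = []
    i = 0

    def add(labels: RiskFactorVector) -> None:
        nonlocal i
        records.append(
            AdjudicatedRecord(
                note=_note(i, f"pt-{i:05d}", f"site-{i % N_SITES:02d}"), labels=labels
            )
        )
        i += 1

    for lab in ("cancer", "weight", "fever", "infection"):
        for _ in range(MULTILEVEL_COUNTS[lab][0]):
            add(RiskFactorVector(**{lab: 1}))
    for k in range(MULTILEVEL_COUNTS["abreflex"][0]):
        bowel = 1 if k < MULTILEVEL_COUNTS["bowel"][0] else 0
        add(RiskFactorVector(abreflex=1, bowel=bowel))
    assert i == ANY_POSITIVE_NOTES
    for _ in range(NULL_NOTES):
        add(RiskFactorVector())
    assert i == N_NOTES
    return records


def positive_rate_batch(
    n_total: int, n_positive: int, prefix: str = "batch"
) -> tuple[list[ClinicalNote], dict[str, RiskFactorVector]]:
    """A batch of notes with an exact hidden positive count (abreflex=1)."""
    notes, gold = [], {}
    for i in range(n_total):
        note = ClinicalNote(
            note_id=f"{prefix}-{i:05d}", patient_id=f"pt-{i:05d}",
            site_id="site-00", text=f"synthetic placeholder note {i}",
        )
        notes.append(note)
        gold[note.note_id] = RiskFactorVector(abreflex=1 if i < n_positive else 0)
    return notes, gold
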