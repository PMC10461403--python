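import numpy as np
import pytest

from chunkclin.datatypes import LABELS, AdjudicatedRecord, ClinicalNote, RiskFactorVector
from chunkclin.synthetic_notes import (
    LengthDistribution,
    SyntheticCorpusSpec,
    generate_corpus,
    records_to_adjudicated,
)


def separable_spec(seed: int = 0, n_notes: int = 300, **overrides) -> SyntheticCorpusSpec:
    """A small, clearly separable corpus: short notes, balanced-ish labels."""
    kwargs = dict(
        n_notes=n_notes,
        null_fraction=0.5,
        label_marginals={lab: 0.12 for lab in LABELS},
        length=LengthDistribution(
            mu=float(np.log(40)), sigma=0.5, min_tokens=10, max_tokens=120
        ),
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticCorpusSpec(**kwargs)


@pytest.fixture(scope="session")
def separable_records() -> list[AdjudicatedRecord]:
    return records_to_adjudicated(generate_corpus(separable_spec(seed=3)))


@pytest.fixture
def tiny_corpus() -> list[AdjudicatedRecord]:
    """Five hand-written notes with known labels."""

    def rec(i, patient, site, text, **labels):
        return AdjudicatedRecord(
            note=ClinicalNote(
                note_id=f"n{i}", patient_id=patient, site_id=site, text=text
            ),
            labels=RiskFactorVector(**labels),
        )

    return [
        rec(0, "p0", "s0", "routine visit back pain improving"),
        rec(1, "p0", "s0", "history of cancer noted on chart", cancer=1),
        rec(2, "p1", "s0", "pt has fever and chills", fever=1),
        rec(3, "p2", "s1", "unexplained weight loss of ten pounds", weight=1),
        rec(4, "p3", "s1", "absent ankle reflex both legs", abreflex=1),
    ]
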