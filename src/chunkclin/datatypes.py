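"""Core domain types.

The six lower-back-pain risk factors ("red flags") are fixed, in this order:

    cancer    — history of cancer
    weight    — unexplained weight loss
    fever     — signs of fever
    infection — recent infection
    bowel     — loss of bowel or bladder control
    abreflex  — abnormal reflexes / loss of muscle power in the legs

A note with none of the six is the *null class*. The order above is the
canonical label order used by every array-valued API in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError

LABELS: tuple[str, ...] = ("cancer", "weight", "fever", "infection", "bowel", "abreflex")

#: Human-readable definitions, used as query fallbacks during STS sampling.
LABEL_DEFINITIONS: dict[str, str] = {
    "cancer": "history of cancer or known malignancy",
    "weight": "unexplained or unintentional weight loss",
    "fever": "fever or febrile illness",
    "infection": "recent infection",
    "bowel": "loss of bowel or bladder control or incontinence",
    "abreflex": "abnormal reflexes or loss of muscle power in the legs",
}


@dataclass(frozen=True)
class RiskFactorVector:
    """Binary indicator per risk factor; all-zero means the null class."""

    cancer: int = 0
    weight: int = 0
    fever: int = 0
    infection: int = 0
    bowel: int = 0
    abreflex: int = 0

    def __post_init__(self) -> None:
        for name in LABELS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise IntegrityError(f"label {name!r} must be 0 or 1, got {v!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RiskFactorVector":
        return cls(**{name: int(d.get(name, 0)) for name in LABELS})

    @classmethod
    def from_array(cls, a) -> "RiskFactorVector":
        a = list(a)
        if len(a) != len(LABELS):
            raise IntegrityError(f"expected {len(LABELS)} label slots, got {len(a)}")
        return cls(**{name: int(v) for name, v in zip(LABELS, a)})

    def to_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in LABELS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in LABELS], dtype=np.int64)

    @property
    def is_null(self) -> bool:
        return all(getattr(self, name) == 0 for name in LABELS)

    def positive_labels(self) -> tuple[str, ...]:
        return tuple(name for name in LABELS if getattr(self, name) == 1)


@dataclass
class ClinicalNote:
    """One free-text clinical encounter note."""

    note_id: str
    patient_id: str
    site_id: str
    text: str
    note_type: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise IntegrityError(f"note {self.note_id!r} has empty text")


@dataclass
class Annotation:
    """One annotator's labels for one note, with evidence snippets.

    ``rationales`` is a list of ``(label, snippet)`` pairs; every rationale's
    label must be positive in ``labels``.
    """

    note_id: str
    annotator_id: str
    labels: RiskFactorVector
    rationales: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, _snippet in self.rationales:
            if label not in LABELS:
                raise IntegrityError(f"unknown rationale label {label!r}")
            if getattr(self.labels, label) != 1:
                raise IntegrityError(
                    f"rationale for label {label!r} on note {self.note_id!r} "
                    "but that label is 0"
                )

    def check_rationales_in_text(self, text: str, strict: bool = False) -> None:
        """Verify rationale snippets occur verbatim in the note text.

        Strict for synthetic data; warn-only for imported data, where
        annotators may have lightly edited the snippet.
        """
        for label, snippet in self.rationales:
            if snippet not in text:
                msg = (
                    f"rationale {snippet!r} ({label}) is not a substring of "
                    f"note {self.note_id!r}"
                )
                if strict:
                    raise IntegrityError(msg)
                warnings.warn(msg, stacklevel=2)


@dataclass
class AdjudicatedRecord:
    """Gold labels for one note after dual annotation and arbitration."""

    note: ClinicalNote
    labels: RiskFactorVector
    rationales: list[tuple[str, str]] = field(default_factory=list)
    provenance: str = "agreed"  # "agreed" | "arbitrated"

    def __post_init__(self) -> None:
        if self.provenance not in ("agreed", "arbitrated"):
            raise IntegrityError(f"invalid provenance {self.provenance!r}")
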