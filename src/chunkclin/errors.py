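"""Exception hierarchy for chunkclin."""


class ChunkclinError(Exception):
    """Base class for all chunkclin errors."""


class SchemaError(ChunkclinError):
    """A file is missing required columns/fields."""


class IntegrityError(ChunkclinError):
    """Data violates a corpus invariant (duplicate ids, empty text, ...)."""


class UnresolvedDisagreementError(ChunkclinError):
    """Two annotators disagree and no arbiter annotation was supplied."""

    def __init__(self, note_id: str, conflicting_labels: list[str]):
        self.note_id = note_id
        self.conflicting_labels = list(conflicting_labels)
        super().__init__(
            f"annotators disagree on note {note_id!r} for labels "
            f"{', '.join(conflicting_labels)} and no arbiter was supplied"
        )


class SpecError(ChunkclinError):
    """A synthetic-corpus specification is invalid."""


class ConfigError(ChunkclinError):
    """A model/sampling/evaluation configuration is invalid."""


class DegenerateSplitError(ChunkclinError):
    """A training split has no positive notes; downsampling is undefined."""


class UndefinedRateError(ChunkclinError):
    """Enrichment rate requested for an empty batch."""


class EncoderError(ChunkclinError):
    """A sentence encoder failed while embedding a batch."""


class TokenizationError(ChunkclinError):
    """The tokenizer failed on a note."""
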