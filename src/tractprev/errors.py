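"""Exception hierarchy shared across the package."""


class TractPrevError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TractPrevError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidInputError(TractPrevError, ValueError):
    """An input object is empty, malformed or inconsistent."""


class MissingSeedTermError(TractPrevError, KeyError):
    """A ranking seed term is absent from the embedding vocabulary."""

    def __init__(self, term: str):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"seed term not in embedding vocabulary: {self.term!r}"


class UnlabeledTermError(TractPrevError, KeyError):
    """A ranked term has no relevance label during keyword selection."""

    def __init__(self, term: str):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:
        return f"ranked term has no relevance label: {self.term!r}"


class UndefinedSimilarityError(TractPrevError, ValueError):
    """Cosine similarity requested against a zero vector."""


class UndefinedCorrelationError(TractPrevError, ValueError):
    """Pearson correlation requested on a zero-variance vector."""


class AlignmentError(TractPrevError, ValueError):
    """Row sets or vector lengths do not line up."""


class MissingDataError(TractPrevError, ValueError):
    """Required rows or cells are absent."""


class SchemaError(TractPrevError, ValueError):
    """Duplicate or conflicting column names."""


class InconsistentIndexError(TractPrevError, KeyError):
    """A neighbor index does not cover every feature-table row."""


class EmptyResultError(TractPrevError, RuntimeError):
    """A filtering step removed every tract."""


class ModelStateError(TractPrevError, RuntimeError):
    """An operation requires a fitted model handle."""
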