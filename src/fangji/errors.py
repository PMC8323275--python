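"""Exception hierarchy for the fangji package."""


class FangjiError(Exception):
    """Base class for all package-specific errors."""


class CorpusParseError(FangjiError):
    """A corpus line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class DuplicateIdError(FangjiError):
    """Two records in one corpus share a formula_id."""


class DictionaryError(FangjiError):
    """A term-dictionary or unit-table file failed validation."""


class ExtractionError(FangjiError):
    """A semi-structured text block has no recognizable composition."""


class FeatureError(FangjiError):
    """A feature vector could not be computed (missing dose, absent piece)."""


class FitError(FangjiError):
    """The weight-model fit is infeasible (too few rows, rank deficiency)."""


class QueryError(FangjiError):
    """A retrieval query is malformed (empty, contradictory year range)."""
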