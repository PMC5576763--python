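"""Exception hierarchy for input validation and degenerate statistics."""


class EqtlCausalError(Exception):
    """Base class for all package errors."""


class ValidationError(EqtlCausalError):
    """Malformed or inconsistent input (shapes, types, unknown IDs)."""


class ParseError(ValidationError):
    """File-level parse failure; carries the offending line when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
            if line is not None:
                prefix += f":{line}"
            prefix += ": "
        super().__init__(prefix + message)


class DegenerateInputError(EqtlCausalError):
    """Input is formally valid but statistically unusable (constant rows,
    single-category genotypes, identical LLR samples)."""


class InapplicableTestError(EqtlCausalError):
    """The analytical null law has non-positive degrees of freedom at this
    (n, n_v), so the test cannot be run."""


class UndefinedMetricError(EqtlCausalError):
    """A metric has no defined value (e.g. one-class groundtruth)."""
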