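"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration errors -> 1, input
validation errors -> 2, total backend failure -> 3.
"""


class ClinexError(Exception):
    """Base class for all package errors."""


class InputError(ClinexError):
    """A required input (file, directory) is missing or unreadable."""


class ValidationError(ClinexError):
    """An input violates a structural invariant (duplicate ids, bad records)."""


class ConfigurationError(ClinexError):
    """A config value is missing or inconsistent (credentials, unknown extractor)."""


class DegenerateInputError(ClinexError):
    """An operation received input outside its mathematical domain."""


class BackendError(ClinexError):
    """A single extractor backend failed; carries the extractor id so the
    ensemble can continue with the remaining backends."""

    def __init__(self, extractor_id: str, message: str):
        super().__init__(f"[{extractor_id}] {message}")
        self.extractor_id = extractor_id


class ParseError(BackendError):
    """A backend returned a payload that could not be parsed."""


class AllBackendsFailedError(ClinexError):
    """Every extractor in the roster failed; the run cannot proceed."""
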