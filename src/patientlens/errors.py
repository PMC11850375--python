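"""Exception hierarchy.

Backend failures are deliberately distinguishable from low scores: a scorer
that cannot run raises :class:`BackendError`, it never returns 0.0.
"""


class PatientLensError(Exception):
    """Base class for all package errors."""


class RecordError(PatientLensError):
    """A malformed input record (carries the 1-based line number)."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class ConfigurationError(PatientLensError):
    """Invalid or unresolvable configuration (unknown root, bad distribution...)."""


class BackendError(PatientLensError):
    """A model backend failed; not the same as a low confidence score."""


class ContractViolationError(PatientLensError):
    """An operation was called outside its stated precondition."""
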