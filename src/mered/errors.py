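"""Exception types shared across the package."""


class MeredError(Exception):
    """Base class for package errors."""


class ValidationError(MeredError):
    """Invalid user input: malformed records, out-of-range probabilities,
    inconsistent axes, unparseable structure strings."""


class ConvergenceError(MeredError):
    """Every optimizer start failed; carries per-start diagnostics."""

    def __init__(self, message, start_log=None):
        super().__init__(message)
        self.start_log = start_log or []
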