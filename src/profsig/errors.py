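"""Exception hierarchy."""


class ProfsigError(Exception):
    """Base class for all package errors."""


class InputError(ProfsigError):
    """Invalid input data (empty files, bad symbols, impossible requests)."""


class FormatError(ProfsigError):
    """Malformed file content (ragged alignments, corrupt profile files)."""


class ConditionError(ProfsigError):
    """A mathematical precondition does not hold (e.g. no positive root)."""


class FitError(ProfsigError):
    """A statistical fit failed or did not converge."""


class GenerationError(ProfsigError):
    """Random profile generation could not satisfy the requested targets."""
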