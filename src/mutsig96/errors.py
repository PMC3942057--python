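"""Exception hierarchy mapped to CLI exit codes."""


class MutsigError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(MutsigError):
    """Bad arguments, malformed input, or an out-of-range parameter."""

    exit_code = 2


class DataIntegrityError(MutsigError):
    """Input data contradicts itself (e.g. ref allele != reference genome)."""

    exit_code = 3


class InsufficientDataError(MutsigError):
    """Too few observations to run the requested computation."""

    exit_code = 4


class SizingError(ValidationError):
    """A simulated contig is too short to host the requested mutations."""


class ConstantInputError(InsufficientDataError):
    """A statistic is undefined because an input vector is constant."""
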