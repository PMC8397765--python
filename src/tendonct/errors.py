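"""Exception hierarchy shared across the pipeline.

Validation errors (bad inputs, impossible geometry) map to CLI exit code 2;
computation errors (the algorithm cannot produce a result on valid input,
e.g. "no edges detected") map to exit code 3.
"""


class TendonCTError(Exception):
    """Base class for all package errors."""


class ValidationError(TendonCTError):
    """Input or configuration violates a precondition."""

    exit_code = 2


class ComputationError(TendonCTError):
    """A valid input on which the requested quantity is undefined."""

    exit_code = 3
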