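"""Exception hierarchy.

``InputError`` marks malformed or inconsistent caller input (wrong shapes,
missing angles, mismatched artifacts).  ``DomainError`` marks inputs that are
structurally valid but mathematically degenerate for the requested operation
(zero-norm strides, all-zero spectra, zero spread of log-distances).
"""


class GaitDIError(Exception):
    """Base class for all package errors."""


class InputError(GaitDIError, ValueError):
    """Malformed, incomplete, or mutually inconsistent input."""


class DomainError(GaitDIError, ValueError):
    """Structurally valid input outside the mathematical domain of an operation."""
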