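"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems (bad inputs,
contract violations) exit 2, I/O problems exit 3, numerical degeneracies
(zero-variance signals, singular correlations) exit 4.
"""


class CchpError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CchpError):
    """Input violates a documented contract (shape, range, uniqueness...)."""


class DegenerateSignalError(CchpError):
    """A signal or feature column is numerically degenerate (e.g. zero variance)."""
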