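"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: DataError -> 3, ConvergenceError -> 4.
"""


class PetkitError(Exception):
    """Base class for all toolkit errors."""


class DataError(PetkitError):
    """Invalid, inconsistent, or malformed input data."""


class ConvergenceError(PetkitError):
    """A numerical fit failed to converge to an acceptable solution."""
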