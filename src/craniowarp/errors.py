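"""Exception hierarchy.

InputError covers malformed or inconsistent user data (CLI exit code 2);
NumericalError covers ill-conditioned or degenerate computations (exit code 3).
"""


class CranioWarpError(Exception):
    """Base class for all package errors."""


class InputError(CranioWarpError):
    """Invalid, missing or inconsistent input data."""


class NumericalError(CranioWarpError):
    """Degenerate geometry or an ill-conditioned linear system."""
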