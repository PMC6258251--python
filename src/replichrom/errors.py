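"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`InfeasibleParameterError` -> 3.
"""


class ReplichromError(Exception):
    """Base class for all package errors."""


class InputError(ReplichromError):
    """Malformed or inconsistent input data (bad BED line, mismatched grids...)."""


class InfeasibleParameterError(ReplichromError):
    """Parameters that cannot be satisfied (e.g. anchor packing that does not fit)."""
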