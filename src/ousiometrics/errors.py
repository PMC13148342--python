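"""Exception hierarchy.

Three failure families map onto distinct CLI exit codes: I/O problems
(missing or unwritable files), validation problems (bad user data), and
contract problems (a caller violated an operation's precondition).
"""


class OusiometricsError(Exception):
    """Base class for all package errors."""


class InputError(OusiometricsError):
    """A file is missing, unreadable, unwritable, or wholly unparseable."""


class ValidationError(OusiometricsError):
    """User-supplied data violates a documented invariant."""


class ContractError(OusiometricsError):
    """An operation was called outside its precondition."""
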