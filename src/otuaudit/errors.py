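"""Exception hierarchy shared across the package.

The CLI maps :class:`FormatError` and :class:`InputError` to exit code 1
(user-correctable input problems) and anything else to exit code 2.
"""


class OtuAuditError(Exception):
    """Base class for all errors raised by otuaudit."""


class FormatError(OtuAuditError):
    """A file violates its format contract (syntax or invariant)."""


class InputError(OtuAuditError):
    """Arguments or in-memory inputs violate an operation's precondition."""


class UnknownIdError(InputError, KeyError):
    """A sequence/leaf/OTU identifier was not found where required."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class UndefinedDistanceError(OtuAuditError):
    """A distance has no defined value (zero countable columns, etc.)."""


class SaturationError(UndefinedDistanceError):
    """A p-distance is at or beyond the model's saturation point."""
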