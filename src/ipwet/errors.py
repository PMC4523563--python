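"""Exception hierarchy.

All package-specific failures derive from :class:`IpwetError` so callers
(and the CLI) can distinguish validation problems from I/O problems.
"""


class IpwetError(Exception):
    """Base class for all errors raised by this package."""


class TapeValidationError(IpwetError, ValueError):
    """A tape specification violates the partition/ordering invariants."""


class OutOfRangeError(IpwetError, ValueError):
    """A height or weight falls outside the tape's covered range."""


class CohortFormatError(IpwetError, ValueError):
    """A cohort table is malformed (missing column, bad value, bad row)."""


class RecalibrationError(IpwetError, ValueError):
    """A recalibration stage cannot proceed (degenerate zone, bad fit...)."""
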