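"""Exception hierarchy shared across the package.

All errors raised on bad user input derive from :class:`RevscenError`, so the
CLI can map them to stable exit codes (2 for input/format problems, 3 for a
refused search cap).
"""


class RevscenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RevscenError):
    """Malformed text input (arrangement files, marker tables, configs)."""


class InputError(RevscenError):
    """Structurally valid input that violates a precondition."""


class ConstraintError(RevscenError):
    """A declarative constraint (junction, colocation) cannot be satisfied."""


class CapExceededError(RevscenError):
    """A search or enumeration refused to run past its configured cap."""


class DerivedJunctionError(RevscenError):
    """A breakpoint region whose flanks are not ancestrally adjacent was used
    where an ancestral-gap computation was requested."""


class IntegrityError(RevscenError):
    """A packaged fixture failed its internal consistency checks."""
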