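"""Exception hierarchy shared across the pipeline.

All pipeline-raised exceptions derive from :class:`TrapcycleError` so that
callers (notably the CLI) can distinguish user-input problems from bugs.
"""


class TrapcycleError(Exception):
    """Base class for all errors raised by this package."""


class TableFormatError(TrapcycleError):
    """A tabular input file is structurally malformed (wrong field count,
    non-numeric cell, missing header column)."""


class ValidationError(TrapcycleError):
    """Input parses but violates a domain invariant (duplicate IDs,
    out-of-range circadian time, inconsistent replicate design)."""


class ContractError(TrapcycleError):
    """A function was called with arguments violating its precondition."""
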