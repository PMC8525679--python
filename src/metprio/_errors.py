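"""Exception hierarchy shared across the package.

``DataError`` marks problems with user-supplied inputs (malformed tables,
unresolvable ids, infeasible requests); the CLI maps it to exit code 3.
"""


class MetprioError(Exception):
    """Base class for all package-specific errors."""


class DataError(MetprioError):
    """Invalid or inconsistent input data."""


class StageError(MetprioError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage={stage}] {message}")
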