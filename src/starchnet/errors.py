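"""Exception hierarchy shared across the package.

The command-line layer maps these onto exit codes (config errors → 2,
format errors → 3, stage failures → 4); library users can catch
:class:`StarchnetError` to intercept everything.
"""


class StarchnetError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(StarchnetError):
    """An invalid configuration value; the message names the field."""


class FormatError(StarchnetError):
    """A structurally invalid input file (TSV/GMT/graph/list)."""


class InputError(StarchnetError):
    """Semantically invalid inputs to an operation (mismatched gene sets,
    empty groups, unknown identifiers, ...)."""


class StageError(StarchnetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
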