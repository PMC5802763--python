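"""Exception hierarchy.

Validation problems (bad inputs, bad configuration) and computation problems
(a stage that cannot produce a result) are kept distinct so the command-line
layer can map them to distinct exit codes.
"""


class PolyhybError(Exception):
    """Base class for all package errors."""


class ValidationError(PolyhybError, ValueError):
    """Malformed or inconsistent input data or parameters."""


class ConfigError(ValidationError):
    """Invalid roles/threshold configuration."""


class ComputationError(PolyhybError, RuntimeError):
    """A stage could not compute its result (e.g. undefined summary)."""


class StageError(ComputationError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
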