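"""Exception hierarchy shared by all pipeline stages.

``ConfigurationError`` and ``InputError`` are *validation* failures (CLI exit
code 2); anything else that escapes a stage is a runtime failure (exit 1).
"""


class PPCVError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(PPCVError, ValueError):
    """A parameter object, config file or design violates its schema."""


class InputError(PPCVError, ValueError):
    """Input data (image, mask, polygon, table) violates a precondition."""


class FormatError(InputError):
    """An on-disk artifact does not match its declared format/geometry."""


class StageError(PPCVError, RuntimeError):
    """A pipeline stage failed; carries the stage name and input id."""

    def __init__(self, stage: str, detail: str, input_id: str | None = None):
        self.stage = stage
        self.input_id = input_id
        where = f"{stage}[{input_id}]" if input_id is not None else stage
        super().__init__(f"{where}: {detail}")
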