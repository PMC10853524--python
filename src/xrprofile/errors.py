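"""Exception hierarchy."""


class XRProfileError(Exception):
    """Base class for all package errors."""


class InputError(XRProfileError):
    """Malformed or inconsistent input data (file format, coordinates, names)."""


class PipelineStageError(XRProfileError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
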