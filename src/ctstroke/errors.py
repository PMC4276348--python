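"""Exception hierarchy shared across the pipeline stages."""


class CTStrokeError(Exception):
    """Base class for all errors raised by this package."""


class InputError(CTStrokeError):
    """Unreadable, missing or structurally invalid input."""


class UnsupportedFormatError(InputError):
    """Input file is readable but not a format the reader supports."""


class ParameterError(CTStrokeError):
    """A tunable parameter is outside its legal range."""


class DegenerateInputError(CTStrokeError):
    """Input is valid but degenerate for the requested operation."""


class ExtractionError(CTStrokeError):
    """Brain-tissue extraction could not find an intracranial component."""


class EmptyHistogramError(CTStrokeError):
    """No pixels were available to build an intensity histogram."""


class PipelineStageError(CTStrokeError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
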