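"""Exception types shared across the pipeline stages."""


class NetprioError(Exception):
    """Base class for all package errors."""


class ParseError(NetprioError):
    """An input file could not be parsed; message names the offending line."""


class UndefinedDistanceError(NetprioError):
    """Closest distance is undefined (no in-graph disease gene to reach)."""


class EmptyBackgroundError(NetprioError):
    """A cell type has no background gene above the expression cut-off."""


class StageError(NetprioError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
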