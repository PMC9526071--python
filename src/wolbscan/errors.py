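"""Exception hierarchy.

Every error raised on purpose by wolbscan derives from :class:`WolbscanError`
so callers (and the CLI) can distinguish expected failure modes from bugs.
"""


class WolbscanError(Exception):
    """Base class for all wolbscan errors."""


class ConfigError(WolbscanError):
    """Invalid configuration (bad parameter value, unknown key, ...)."""


class ParseError(WolbscanError):
    """A file could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class PipelineError(WolbscanError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
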