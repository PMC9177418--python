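"""Exception hierarchy shared across the pipeline stages."""


class PanbgcError(Exception):
    """Base class for all panbgc errors."""


class InputError(PanbgcError):
    """A value passed to an operation violates its preconditions."""


class ParseError(PanbgcError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ConfigError(PanbgcError):
    """A configuration is internally inconsistent or infeasible."""


class StageError(PanbgcError):
    """A pipeline stage failed; the message names the stage."""


class CrossReferenceError(PanbgcError):
    """A record refers to an entity (genome, gene, bin) that does not exist."""
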