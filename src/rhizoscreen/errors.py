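"""Exception hierarchy shared across the package.

Two user-facing categories matter for the CLI exit codes: configuration /
usage problems (exit 1) and malformed or inconsistent data (exit 2).
"""


class RhizoscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RhizoscreenError):
    """Invalid configuration or parameter combination (CLI exit code 1)."""


class DataError(RhizoscreenError):
    """Malformed, inconsistent, or missing input data (CLI exit code 2)."""


class ParseError(DataError):
    """A file could not be parsed; carries file context and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class PrerequisiteError(DataError):
    """A pipeline stage was invoked before the stage it depends on."""

    def __init__(self, stage: str, missing: str, run_first: str):
        super().__init__(
            f"stage '{stage}' requires '{missing}' which was not found; "
            f"run stage '{run_first}' first"
        )
        self.stage = stage
        self.run_first = run_first
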