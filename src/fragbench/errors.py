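"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 1, DataError (and
subclasses) -> 2.
"""


class FragbenchError(Exception):
    """Base class for all package errors."""


class ConfigError(FragbenchError):
    """Invalid configuration or usage."""


class DataError(FragbenchError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """Malformed file content; carries file context where known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class LayoutMismatchError(DataError):
    """Two intensity vectors do not share the canonical fragment layout."""


class UndefinedSimilarityError(DataError):
    """Similarity metric undefined for the given vectors (all-zero or
    zero-variance input)."""

    def __init__(self, message: str, code: str):
        super().__init__(message)
        self.code = code
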