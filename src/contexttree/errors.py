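"""Error taxonomy shared by the library and the command line.

Each error class carries the process exit code the CLI maps it to, so
library callers and shell callers see the same failure classification.
"""


class ContextTreeError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class UsageError(ContextTreeError):
    """Invalid combination of options or an operation misuse."""

    exit_code = 2


class InputError(ContextTreeError):
    """Missing files, unknown identifiers, inconsistent input tables."""

    exit_code = 3


class ParseError(ContextTreeError):
    """Malformed content inside an input file; names the offending line."""

    exit_code = 4

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}:" + (f"{line}: " if line is not None else " ")
        super().__init__(loc + message)
        self.path = path
        self.line = line


class NoMatchesError(ContextTreeError):
    """A query matched no gene in any loaded genome (not a crash)."""

    exit_code = 5
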