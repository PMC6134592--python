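"""Exception hierarchy for exocube."""


class ExocubeError(Exception):
    """Base class for all exocube errors."""


class FormatError(ExocubeError):
    """A delimited-text file does not follow the upload dialect."""


class RowError(FormatError):
    """A single data row is malformed (bad action word, bad number, ...)."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line
        self.row_message = message


class DuplicateObservationError(ExocubeError):
    """Two observations share the same (metabolite, organism, environment)."""

    def __init__(self, key):
        super().__init__(f"duplicate observation for {key!r}")
        self.key = key


class UnknownEntityError(ExocubeError, LookupError):
    """A referenced metabolite/organism/environment is not in the datacube."""


class AmbiguousMetaboliteError(ExocubeError, LookupError):
    """A metabolite query matched more than one compound.

    Carries the candidate names so callers can disambiguate.
    """

    def __init__(self, query: str, matches):
        self.query = query
        self.matches = list(matches)
        super().__init__(
            f"query {query!r} matches {len(self.matches)} metabolites: "
            + ", ".join(self.matches)
        )


class StorageError(ExocubeError):
    """The embedded database file is missing, corrupt or inconsistent."""


class SpecError(ExocubeError, ValueError):
    """A simulation spec violates its own constraints."""


class InputError(ExocubeError, ValueError):
    """Replicate abundance input is empty or non-finite/negative."""
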