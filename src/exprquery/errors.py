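"""Exception hierarchy.

Every error a user can trigger maps to a stable CLI exit code via the
``exit_code`` class attribute; the CLI prints one greppable line per error.
"""


class QueryToolError(Exception):
    """Base class for all user-facing errors."""

    exit_code = 1


class ParseError(QueryToolError):
    """Lexical or syntactic error in a FILTER/SORTER expression.

    Carries the 0-based character ``position`` in the source text where the
    problem was detected.
    """

    exit_code = 2

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ValidationError(QueryToolError):
    """Expression references columns absent from (or of the wrong kind in) the table."""

    exit_code = 3


class SelectionError(QueryToolError):
    """Export/plot selection names unknown rows or non-numeric columns."""

    exit_code = 3


class FixtureError(QueryToolError):
    """Infeasible synthetic-fixture specification (e.g. planted count > n_rows)."""

    exit_code = 3


class InputError(QueryToolError):
    """Unreadable or empty input file."""

    exit_code = 4


class SchemaError(QueryToolError):
    """Malformed table schema: missing key column, duplicate headers, empty identifiers."""

    exit_code = 4


class JoinError(QueryToolError):
    """Datasets cannot be joined: duplicate keys or colliding column names."""

    exit_code = 4


class ConfigError(QueryToolError):
    """Bad or incomplete runtime configuration (registry, templates, paths)."""

    exit_code = 4


class NotFoundError(QueryToolError):
    """A named saved query (or registry dataset) does not exist."""

    exit_code = 5


class StoreConflictError(QueryToolError):
    """Saving a query under a name that already exists, without --overwrite."""

    exit_code = 6
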