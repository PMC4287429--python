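"""Exception hierarchy shared across the package."""


class TagTrieError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TagTrieError):
    """A sequence or database file could not be parsed."""


class ConfigError(TagTrieError):
    """Inconsistent or invalid run configuration (site, tag length, paths)."""


class AlphabetError(TagTrieError):
    """A sequence contained a character outside the supported alphabet."""


class QueryTooLongError(TagTrieError):
    """A query is longer than the tag length the database was built for.

    Reads longer than the stored tag length cannot be mapped; trim them or
    rebuild the database with a larger tag length.
    """


class FixtureError(TagTrieError):
    """A synthetic-data specification is infeasible (e.g. sites do not fit)."""
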