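"""Exception hierarchy.

Every error carries a distinct CLI exit code so shell pipelines can
discriminate schema problems from empty inputs from bad queries.
"""


class StainScoreError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(StainScoreError):
    """An input table is missing a required column or otherwise malformed."""

    exit_code = 2


class ParseError(StainScoreError):
    """A cell value could not be parsed (carries the offending line number)."""

    exit_code = 2


class EmptyInputError(StainScoreError):
    """An input file or record collection contains no usable data."""

    exit_code = 3


class EmptyQueryError(StainScoreError):
    """A query string yielded zero gene symbols."""

    exit_code = 4


class NoGenesMatchedError(StainScoreError):
    """No query symbol matched any gene in the staining table."""

    exit_code = 4

    def __init__(self, unmatched):
        self.unmatched = tuple(unmatched)
        super().__init__(
            "no query genes matched the staining table; unmatched: "
            + ", ".join(self.unmatched)
        )


class EmptyAfterFilterError(StainScoreError):
    """No records survived the reliability (stringency) filter."""

    exit_code = 5


class TooFewProteinsError(StainScoreError):
    """Fewer than four proteins available to define the enriched-set quartile."""

    exit_code = 5


class ConfigurationError(StainScoreError):
    """An invalid run configuration (e.g. list size exceeding the gene universe)."""

    exit_code = 5


class UndefinedScoreError(StainScoreError):
    """A staining score was requested for a cell type with no tested proteins."""

    exit_code = 5
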