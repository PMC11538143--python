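"""Exception hierarchy for the pipeline.

Every error raised on bad scientific input derives from :class:`WashTrendsError`
so callers (and the CLI) can distinguish domain problems from programming bugs.
"""


class WashTrendsError(Exception):
    """Base class for all pipeline errors."""


class FormatError(WashTrendsError):
    """A delimited-table cell or layout could not be parsed."""


class StructuralError(WashTrendsError):
    """A table violates a structural contract (month gaps, duplicates)."""


class DomainError(WashTrendsError):
    """Input is outside the mathematical domain of an operation."""


class DegenerateSequenceError(DomainError):
    """A sequence has zero rank variance, so rank correlation is undefined."""


class CoverageError(DomainError):
    """A yearly aggregate was requested over an incompletely covered year."""


class UndefinedCOVError(DomainError):
    """Every month of an extraction pair has a zero average volume."""

    def __init__(self, months):
        self.months = list(months)
        super().__init__(
            f"COV undefined (both extractions zero) for month index(es) {self.months}"
        )
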