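"""Exception hierarchy shared across the pipeline."""


class LysoquantError(Exception):
    """Base class for all package errors."""


class FormatError(LysoquantError):
    """Input file is not in the expected format."""


class SchemaError(LysoquantError):
    """Tabular input is missing required columns or roles."""


class InvariantError(LysoquantError):
    """A domain-type invariant is violated (e.g. nucleus outside cell)."""


class DomainError(LysoquantError):
    """Arguments outside the mathematical domain of an operation."""


class CapacityError(LysoquantError):
    """A simulation request cannot be placed in the available geometry."""


class NoSignalError(LysoquantError):
    """An operation found no usable signal (empty denominator, empty ROI)."""


class NoContactError(LysoquantError):
    """A force curve never rises above its baseline."""


class FitError(LysoquantError):
    """A model fit failed to converge or produced an inadmissible value."""


class UncountableError(LysoquantError):
    """No dilution plate falls in the countable range."""


class SampleSizeError(LysoquantError):
    """Fewer events than the quantification requires."""
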