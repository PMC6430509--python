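"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`SbipyError`, so callers can catch
one base class; orchestration re-raises with a stage tag.
"""


class SbipyError(Exception):
    """Base class for all package errors."""


# --- compositional primitives ---------------------------------------------

class ZeroOrNegativePartError(SbipyError):
    """A compositional part is zero or negative where strict positivity is required."""


class DegenerateCompositionError(SbipyError):
    """Fewer than two parts: no log-ratio geometry exists."""


class UnknownPartError(SbipyError):
    """A balance node references a part name absent from the composition."""


class InvalidPartitionError(SbipyError):
    """Numerator/denominator subsets overlap or do not form a bifurcating tree."""


# --- feature tables --------------------------------------------------------

class EmptySampleError(SbipyError):
    """A sample row contains only zeros."""


class EmptyFeatureError(SbipyError):
    """A feature column contains only zeros."""


class EmptyTableError(SbipyError):
    """A table has no rows or no columns after validation/filtering."""


class UnknownFeatureError(SbipyError):
    """A referenced feature id is not present in the table."""


# --- weather ---------------------------------------------------------------

class InvalidWeatherError(SbipyError):
    """Malformed daily weather series (negative rainfall, broken calendar)."""


class UndefinedIndexError(SbipyError):
    """An index is mathematically undefined for this input (e.g. SDI with PPT=0)."""


# --- modelling -------------------------------------------------------------

class ConstantPredictorError(SbipyError):
    """A predictor column is constant and cannot be standardized."""


class SingularDesignError(SbipyError):
    """The design matrix is rank deficient."""


class SbiUndefinedError(SbipyError):
    """The species balance index is undefined (an empty positive or negative set)."""


class InsufficientDataError(SbipyError):
    """Too few samples for the requested operation."""


# --- configuration / io ----------------------------------------------------

class ConfigError(SbipyError):
    """Infeasible or inconsistent configuration."""


class ParseError(SbipyError):
    """Malformed input file; message carries line/field context."""
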