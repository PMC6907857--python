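"""Exception hierarchy shared by all pipeline stages."""


class PenliabError(Exception):
    """Base class for all package errors."""


class SchemaError(PenliabError):
    """Input file is missing a mandatory column or declares an unusable header."""


class ParseError(PenliabError):
    """A cell value could not be interpreted; message cites the offending row."""


class ValidationError(PenliabError):
    """Parsed data violate a table invariant (duplicates, missing reference, ...)."""


class EstimationError(PenliabError):
    """A statistic was requested on an empty or unscorable group."""


class SaturationError(PenliabError):
    """A capped liability value was used where a point estimate is required."""


class IdentifiabilityError(PenliabError):
    """The strain-by-phenotype design is disconnected and the fit has no anchor path."""


class DesignError(PenliabError):
    """An experimental design precondition fails (too few dilutions, groups, ...)."""


class PowerError(PenliabError):
    """A group is too small for the requested test."""


class ExtinctionError(PenliabError):
    """The simulated line ran out of viable heterozygous parents."""
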