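"""Exception hierarchy for the methclock pipeline.

Every structural problem with input tables raises a distinct, named error so
callers (and tests) can react to the specific violation rather than parsing
messages.
"""


class MethclockError(Exception):
    """Base class for all package errors."""


class ValidationError(MethclockError):
    """Base class for input-table validation failures."""


class DimensionMismatchError(ValidationError):
    """Matrix shape disagrees with sample sheet or probe annotation."""


class DuplicateIdError(ValidationError):
    """A sample_id or cpg_id occurs more than once."""


class BetaRangeError(ValidationError):
    """A non-missing beta value lies outside [0, 1]."""


class UnknownCodeError(ValidationError):
    """Sex, status or probe-class code outside the closed vocabulary."""


class EmptySelectionError(MethclockError):
    """A filter removed every sample or probe; message names the rule."""


class DegenerateDesignError(MethclockError):
    """Model fitting impossible: constant response, singular design,
    a single grouping level, or too few observations."""


class MissingProbeError(MethclockError):
    """A clock references CpGs absent from the matrix it is applied to."""
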