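"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PhoscaleError` so the CLI can map
failures to a stage-named message and a nonzero exit status.
"""


class PhoscaleError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PhoscaleError):
    """A table does not conform to the expected dialect (e.g. a mandatory
    column is missing)."""


class DesignMismatchError(PhoscaleError):
    """The experiment design references samples absent from a data table."""


class DesignError(PhoscaleError):
    """The experiment design itself is unusable for a requested operation
    (e.g. no control samples at a timepoint)."""


class NormalizationError(PhoscaleError):
    """A sample cannot be normalized (zero quantified values)."""


class ConfigError(PhoscaleError):
    """Invalid or incomplete configuration."""


class InputError(PhoscaleError):
    """Semantically invalid input to an analysis operation (e.g. foreground
    gene set not contained in the background)."""
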