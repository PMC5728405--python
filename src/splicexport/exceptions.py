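"""Exception types shared across the pipeline."""


class SplicexportError(Exception):
    """Base class for all pipeline errors."""


class PlacementError(SplicexportError):
    """Synthetic objects could not be placed without overlap within the retry budget."""


class SchemaError(SplicexportError):
    """An input table is missing required columns, conditions or compartments."""


class FitError(SplicexportError):
    """A model fit is impossible (too few points, zero spread, zero slope)."""


class EmptyResultError(SplicexportError):
    """An operation excluded every cell/record and has nothing to report."""


class ParameterError(SplicexportError):
    """A parameter is outside its documented domain."""
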