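"""Exception hierarchy for the pipeline."""


class AmtPipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(AmtPipeError):
    """Invalid simulation or pipeline configuration."""


class InputError(AmtPipeError):
    """Malformed or inconsistent input data."""


class DegenerateRunError(AmtPipeError):
    """An LC-MS run whose scan axis cannot be normalized (single scan)."""


class DegenerateDesignError(AmtPipeError):
    """A group design that admits no informative label permutation."""


class ColumnError(AmtPipeError):
    """A sample column with too few observed values to normalize."""
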