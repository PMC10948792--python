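"""Exception hierarchy for emocue."""


class EmocueError(Exception):
    """Base class for all emocue errors."""


class SchemaError(EmocueError):
    """Malformed or out-of-vocabulary input data."""


class AxisMismatchError(EmocueError):
    """Two tables (or a table and a prior) disagree on stimulus or emotion axes."""


class DegenerateDataError(EmocueError):
    """Input with no usable statistical content (zero variance, empty condition,
    singular covariance, too few observations)."""
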