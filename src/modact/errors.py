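"""Exception hierarchy shared across the package."""


class ModactError(Exception):
    """Base class for all data/validation errors raised by modact."""


class SchemaError(ModactError):
    """A module-graph file violates the documented JSON schema."""


class GraphValidationError(ModactError):
    """A module graph violates a structural invariant."""


class DataError(ModactError):
    """Tabular input (expression, design, survival, drug map) is malformed."""


class ConvergenceError(ModactError):
    """Fixed-point propagation failed to converge within the iteration cap."""


class ModelError(ModactError):
    """Predictor training, persistence, or application failed."""
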