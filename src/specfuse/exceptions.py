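"""Exception hierarchy for the specfuse pipeline.

Every stage raises a subclass of :class:`SpecfuseError`, so callers (and the
CLI) can catch one type and still let programming errors propagate.
"""


class SpecfuseError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(SpecfuseError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSpectrumError(SpecfuseError, ValueError):
    """A spectrum cannot be normalized (e.g. a constant row under SNV)."""


class AlignmentError(SpecfuseError, ValueError):
    """Row metadata or feature axes of two objects do not line up."""


class RankDeficiencyError(SpecfuseError, ValueError):
    """More latent variables / principal components requested than the data rank."""


class InsufficientReplicatesError(SpecfuseError, ValueError):
    """Fewer than two replicate values where a standard deviation is needed."""


class UndefinedMetricError(SpecfuseError, ValueError):
    """A metric (e.g. R^2 with zero response variance) is undefined."""


class ConfigurationError(SpecfuseError, ValueError):
    """An experiment configuration is internally inconsistent."""


class PipelineStateError(SpecfuseError, RuntimeError):
    """A stateful pipeline step was applied twice or out of order."""
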