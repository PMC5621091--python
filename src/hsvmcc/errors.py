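"""Exception types shared across the package."""


class HsvmccError(Exception):
    """Base class for package-specific errors."""


class ParameterError(HsvmccError, ValueError):
    """A parameter violates a documented precondition."""


class EmptyStreamError(HsvmccError, ValueError):
    """An operation received a stream with no samples."""


class FeatureUndefinedError(HsvmccError, ValueError):
    """A window does not contain enough samples to define a feature."""


class DegenerateSplitError(HsvmccError, ValueError):
    """k-means cannot split: all candidate feature values are identical."""


class PipelineStageError(HsvmccError, RuntimeError):
    """A pipeline stage failed; the stage name is included in the message."""
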