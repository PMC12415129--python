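"""Exception hierarchy.

Every error raised by this package derives from :class:`GcgraderError` so
pipeline drivers can catch one base class and re-raise with stage context.
"""


class GcgraderError(Exception):
    """Base class for all gcgrader errors."""


class ParameterError(GcgraderError, ValueError):
    """An invalid configuration or parameter value."""


class StateError(GcgraderError, RuntimeError):
    """An operation was applied to a matrix in the wrong normalization state."""


class SchemaError(GcgraderError, ValueError):
    """Mismatched shapes, gene sets, or annotation lengths."""


class FormatError(GcgraderError, ValueError):
    """A malformed on-disk file (MTX triplet, sidecar table)."""


class InsufficientDataError(GcgraderError, ValueError):
    """Too few observations for the requested computation."""


class DegenerateCellError(GcgraderError, ValueError):
    """A cell with zero total counts reached a normalization step."""


class MissingGeneError(GcgraderError, KeyError):
    """A requested gene identifier is absent from the matrix."""


class DomainError(GcgraderError, ValueError):
    """A numeric input outside its mathematical domain (e.g. p > 1)."""


class LabelingError(GcgraderError, RuntimeError):
    """Cluster purity labeling produced no usable FS or NFS cluster."""


class TrainingError(GcgraderError, RuntimeError):
    """The classifier cannot be trained on the provided data."""


class EvaluationError(GcgraderError, ValueError):
    """Invalid evaluation input (e.g. empty test set)."""


class QuantificationError(GcgraderError, RuntimeError):
    """FS-percentage estimation failed (e.g. every cell ambiguous)."""


class PipelineError(GcgraderError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage
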