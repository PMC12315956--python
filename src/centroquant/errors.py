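"""Exception hierarchy shared across the pipeline stages."""


class CentroquantError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CentroquantError, ValueError):
    """A parameter violates its documented constraint."""


class GenerationError(CentroquantError):
    """Synthetic-field generation failed (e.g. nucleus packing)."""


class RenderError(CentroquantError):
    """Field content does not fit the configured image geometry."""


class MetadataError(CentroquantError):
    """Image metadata is missing or ambiguous (axis order, units)."""


class UnitError(CentroquantError):
    """A physical pixel/voxel size is required but unknown."""


class MeasurementError(CentroquantError):
    """An ROI measurement could not be taken (e.g. out of bounds)."""


class NoWoundError(CentroquantError):
    """No cell-free band wide enough to be a wound was found."""


class DegenerateDataError(CentroquantError):
    """Input data admit no defined answer (zero variance, empty group)."""


class PipelineError(CentroquantError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
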