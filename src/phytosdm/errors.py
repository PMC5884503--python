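"""Exception hierarchy shared across the package."""


class PhytoSDMError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhytoSDMError):
    """Invalid configuration value or inconsistent option combination."""


class FormatError(PhytoSDMError):
    """Malformed input file (missing columns, bad values, duplicate ids)."""


class DomainError(PhytoSDMError):
    """Value outside the mathematical domain of an operation."""


class SamplingError(PhytoSDMError):
    """Requested more samples than the available population."""


class DegeneracyError(PhytoSDMError):
    """Statistic undefined for degenerate input (e.g. constant values)."""


class GeometryError(PhytoSDMError):
    """Grids do not share dimensions, geotransform, or mask."""


class PipelineError(PhytoSDMError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
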