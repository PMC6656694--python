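"""Exception hierarchy shared across the package."""


class CytomonError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CytomonError):
    """Packaged data or user configuration is missing or inconsistent."""


class FCSFormatError(CytomonError):
    """An FCS file could not be parsed or written."""


class ScaleError(CytomonError):
    """An operation was applied to data on the wrong intensity scale."""


class SimulationConfigError(CytomonError):
    """A synthetic-data configuration is invalid."""


class PipelineStageError(CytomonError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
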