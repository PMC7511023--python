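"""Exception hierarchy for the morphometry pipeline."""


class AlveomorphError(Exception):
    """Base class for all package errors."""


class IngestError(AlveomorphError):
    """Raised when a field image cannot be read or standardized."""


class RoiParseError(AlveomorphError):
    """Raised for malformed ROI files or degenerate polygons."""


class StageError(AlveomorphError):
    """Raised when a mask is passed to a step out of pipeline order."""


class UndefinedReadoutError(AlveomorphError):
    """Raised when a stereological read-out is undefined for the counts
    (e.g. no reference points at all, or intersections absent while
    airspace points are present)."""


class GenerationError(AlveomorphError):
    """Raised when a synthetic image cannot be generated as specified."""


class SamplingError(AlveomorphError):
    """Raised when field sampling cannot satisfy its constraint."""


class StatError(AlveomorphError):
    """Raised for degenerate inputs to the agreement statistics."""


class UsageError(AlveomorphError):
    """Raised for invalid batch configurations (e.g. empty input folder)."""
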