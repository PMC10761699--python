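"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes):
``InputError`` for anything wrong with data or configuration before analysis
starts, and ``AnalysisError`` for failures of the analysis itself (e.g. no
exponential window satisfies the constraints).
"""


class PhenogrowError(Exception):
    """Base class for all package errors."""


class InputError(PhenogrowError):
    """Invalid input data, file format or configuration."""


class FormatError(InputError):
    """A table is missing required columns or is otherwise malformed."""


class AlignmentError(InputError):
    """Absorbance channels do not share a timestamp grid."""

    def __init__(self, well_id: str, time_h: float, channel: object):
        self.well_id = well_id
        self.time_h = time_h
        self.channel = channel
        super().__init__(
            f"well {well_id!r}: channel {channel} has no reading at t={time_h} h"
        )


class ParseError(InputError):
    """A persisted artifact (e.g. calibration JSON) is corrupt or partial."""


class ValidationError(InputError):
    """A value violates a documented precondition (e.g. non-positive count)."""


class ConfigurationError(InputError):
    """Missing or inconsistent run configuration (e.g. no blank wells)."""


class AnalysisError(PhenogrowError):
    """The analysis could not be carried out on otherwise valid inputs."""


class DivisionError(AnalysisError):
    """Abs560 is zero somewhere, so the 430/560 ratio is undefined."""

    def __init__(self, well_id: str, time_h: float):
        self.well_id = well_id
        self.time_h = time_h
        super().__init__(f"well {well_id!r}: Abs560 is 0 at t={time_h} h")


class DetectionError(AnalysisError):
    """No contiguous window satisfies the exponential-phase constraints."""


class FitError(AnalysisError):
    """Too few points for a linear fit in the requested window."""


class CalibrationError(AnalysisError):
    """The ln(GI) vs ln(C) calibration could not be fitted."""


class PredictionError(AnalysisError):
    """Cell counts cannot be predicted (e.g. no positive GI values)."""


class NormalisationError(AnalysisError):
    """Dose-response normalisation failed (no untreated control)."""


class WindowError(AnalysisError):
    """A requested time lies outside the calibration linearity window."""
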