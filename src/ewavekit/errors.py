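"""Exception hierarchy for ewavekit."""


class EwaveError(Exception):
    """Base class for all ewavekit errors."""


class InvalidParametersError(EwaveError, ValueError):
    """Oscillator constants violate their physical bounds (k>0, x0>0, c>=0)."""


class NonPhysicalTriadError(EwaveError, ValueError):
    """A (acceleration time, deceleration time, Vmax) triad that no damped
    recoil wave can produce, e.g. acceleration time longer than deceleration
    time (would require negative damping)."""


class DetectionError(EwaveError):
    """Envelope detection failed (empty or out-of-range window, too few
    accepted samples, non-decelerating tangent, ...)."""


class FitError(EwaveError):
    """Curve fitting could not be performed (too few samples, ...)."""


class NoMatchError(EwaveError):
    """Normalized cross-correlation found no onset above the floor."""


class DicomRegionError(EwaveError):
    """No usable spectral-Doppler ultrasound region in a DICOM file."""


class MissingCalibrationError(DicomRegionError):
    """A Doppler region lacks a physical calibration attribute."""

    def __init__(self, attribute: str):
        self.attribute = attribute
        super().__init__(f"Doppler region lacks calibration attribute {attribute!r}")


class SessionVersionError(EwaveError):
    """A session container was written by an incompatible schema version."""


class StatisticsError(EwaveError, ValueError):
    """Degenerate input to a reproducibility statistic."""
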