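"""Velocity-envelope extraction from calibrated spectral-Doppler strips.

A pulsed-wave Doppler recording is a brightness image: columns are time,
rows are velocity, and pixel brightness encodes how much blood moves at that
velocity at that instant.  The E-wave envelope is recovered by scanning each
column top-down for the first suprathreshold pixel (the fastest blood), with
a jump rule rejecting isolated noise, plus two optional corrections that
shorten the deceleration limb toward clinical practice: zeroing the final
two samples, and substituting the tangent at 70 % of peak velocity for the
fitted deceleration limb.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from skimage.filters import threshold_otsu

from .errors import DetectionError
from .model import PDFParameters, ewave_duration, model_velocity, peak_characteristics

__all__ = [
    "DopplerStrip",
    "DetectionSettings",
    "VelocityTrace",
    "orient_strip",
    "contrast_stretch",
    "detect_envelope",
    "zero_tail",
    "tangent_shorten",
    "read_trace",
    "write_trace",
]


@dataclass
class DopplerStrip:
    """A calibrated pixel matrix of spectral Doppler.

    ``pixels`` is row-major brightness (0–255); ``dt_per_col`` s/px and
    ``dv_per_row`` (cm/s)/px are the physical calibration; ``baseline_row``
    is the zero-velocity row; ``flow_sign`` is +1 when the E-wave lies above
    the baseline (toward row 0).  The velocity of pixel (r, c) is
    ``flow_sign * (baseline_row - r) * dv_per_row``.  Column ``i`` represents
    the pixel-centre time ``(i + 0.5) * dt_per_col``.
    """

    pixels: np.ndarray
    dt_per_col: float
    dv_per_row: float
    baseline_row: int
    flow_sign: int = 1
    source_id: str = ""
    offset_s: float = 0.0  # start time of this strip within its parent recording
    heart_rate: Optional[float] = None  # bpm, from metadata when available

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.dt_per_col <= 0 or self.dv_per_row <= 0:
            raise ValueError("calibration deltas must be positive")
        if not (0 <= self.baseline_row < self.pixels.shape[0]):
            raise ValueError("baseline_row outside the pixel matrix")
        if self.flow_sign not in (+1, -1):
            raise ValueError("flow_sign must be +1 or -1")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_cols * self.dt_per_col

    @property
    def velocity_span(self) -> float:
        """Full velocity range represented by the image, cm/s."""
        return self.n_rows * self.dv_per_row

    def column_times(self) -> np.ndarray:
        """Pixel-centre time of every column, s."""
        return (np.arange(self.n_cols) + 0.5) * self.dt_per_col

    def row_velocity(self, row) -> np.ndarray:
        return self.flow_sign * (self.baseline_row - np.asarray(row)) * self.dv_per_row

    def sweep_speed_warning(self, pixel_pitch_mm: float = 0.25) -> Optional[str]:
        """Warn (return a message) when the time calibration implies a sweep
        speed below the recommended 100 mm/s at the given display pixel
        pitch; low sweep speeds cost temporal resolution."""
        sweep_mm_s = pixel_pitch_mm / self.dt_per_col
        if sweep_mm_s < 100.0:
            return (
                f"implied sweep speed {sweep_mm_s:.0f} mm/s is below the "
                "recommended 100 mm/s; temporal resolution may be poor"
            )
        return None


@dataclass
class DetectionSettings:
    """User-adjustable inputs to envelope detection.

    ``t_start``/``t_end`` bound the analysed window (s); ``threshold`` is the
    brightness at which a pixel counts as flow (None → Otsu threshold of the
    window); ``max_jump`` is the largest velocity change accepted between a
    candidate and the last accepted sample, cm/s (None → 25 % of the strip's
    velocity span).  ``zero_tail`` and ``tangent_shorten`` enable the two
    deceleration-shortening corrections (both on by default).
    """

    t_start: float = 0.0
    t_end: Optional[float] = None
    threshold: Optional[float] = None
    max_jump: Optional[float] = None
    zero_tail: bool = True
    tangent_shorten: bool = True

    def __post_init__(self):
        if self.t_end is not None and self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        if self.threshold is not None and not (0 <= self.threshold <= 255):
            raise ValueError("threshold must lie in the 0-255 intensity range")


@dataclass
class VelocityTrace:
    """Detected time–velocity envelope samples.

    One sample per analysed column.  Samples rejected by the jump rule (or
    columns with no suprathreshold pixel, velocity NaN) are retained with
    ``accepted=False`` for reference.
    """

    times: np.ndarray
    velocities: np.ndarray
    accepted: np.ndarray
    settings: Optional[DetectionSettings] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if not (len(self.times) == len(self.velocities) == len(self.accepted)):
            raise ValueError("times, velocities and accepted must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    @property
    def accepted_times(self) -> np.ndarray:
        return self.times[self.accepted]

    @property
    def accepted_velocities(self) -> np.ndarray:
        return self.velocities[self.accepted]

    @property
    def onset(self) -> float:
        """Absolute time of flow onset, s.

        For detected traces this is the detection window start the user (or
        template matching) placed at the onset of flow; samples sit at pixel
        centres half a column later.  For plain traces it is the first
        sample."""
        if self.settings is not None:
            return self.settings.t_start
        return float(self.times[0])

    def relative_times(self) -> np.ndarray:
        """Accepted times re-referenced so flow onset is t = 0."""
        return self.accepted_times - self.onset

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "velocity_cm_s": self.velocities,
             "accepted": self.accepted}
        )


def orient_strip(strip: DopplerStrip) -> DopplerStrip:
    """Normalize a strip so the E-wave lies above the baseline (flow_sign +1).

    Idempotent; the velocity of every pixel is preserved by flipping the
    matrix and re-indexing the baseline."""
    if strip.flow_sign == 1:
        return strip
    return replace(
        strip,
        pixels=strip.pixels[::-1].copy(),
        baseline_row=strip.n_rows - 1 - strip.baseline_row,
        flow_sign=1,
    )


def contrast_stretch(strip: DopplerStrip, low_pct: float = 1.0,
                     high_pct: float = 99.0) -> DopplerStrip:
    """Linear contrast stretch between two intensity percentiles.

    Purely a display/detection aid: geometry and calibration are untouched.
    A constant image is returned unchanged with a warning."""
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(strip.pixels, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("contrast_stretch: degenerate (constant) image, returned unchanged")
        return strip
    stretched = np.clip(np.rint((strip.pixels.astype(float) - lo)
                                * (255.0 / (hi - lo))), 0, 255)
    return replace(strip, pixels=stretched.astype(strip.pixels.dtype
                                                  if np.issubdtype(strip.pixels.dtype, np.integer)
                                                  else np.uint8))


def detect_envelope(strip: DopplerStrip, settings: DetectionSettings) -> VelocityTrace:
    """Top-down first-crossing envelope detection with a jump rule.

    Each column in the detection window is scanned from row 0 toward the
    baseline for the first pixel at or above the threshold; its velocity is
    the column's candidate.  A candidate differing from the last *accepted*
    velocity by more than ``max_jump`` is kept but flagged rejected, so an
    isolated noise pixel does not poison subsequent columns.  The reference
    for the first sample is zero: flow is about to begin, so its velocity
    must start near zero.
    """
    strip = orient_strip(strip)
    times = strip.column_times()
    t_end = settings.t_end if settings.t_end is not None else times[-1]
    if settings.t_start > times[-1] or t_end < times[0]:
        raise DetectionError("detection window lies outside the strip")
    mask = (times >= settings.t_start) & (times <= t_end)
    cols = np.nonzero(mask)[0]
    if cols.size == 0:
        raise DetectionError("detection window contains no columns")

    window = strip.pixels[: strip.baseline_row + 1, cols]
    if settings.threshold is not None:
        thr = settings.threshold
    else:
        # Otsu separates background speckle from the filled spectral band,
        # but the speckle tail hugs the Otsu cut; the midpoint of the two
        # class means clears it with a wide margin on both sides.
        vals = window.ravel()
        if np.ptp(vals) > 0:
            cut = float(threshold_otsu(vals))
            thr = 0.5 * (vals[vals <= cut].mean() + vals[vals > cut].mean())
        else:
            thr = np.inf
    max_jump = (settings.max_jump if settings.max_jump is not None
                else 0.25 * strip.velocity_span)

    n = cols.size
    velocities = np.full(n, np.nan)
    accepted = np.zeros(n, dtype=bool)
    last_accepted = 0.0  # onset reference: flow starts from rest
    for j, col in enumerate(cols):
        column = strip.pixels[: strip.baseline_row + 1, col]
        hits = np.nonzero(column >= thr)[0]
        if hits.size == 0:
            continue
        v = float(strip.row_velocity(hits[0]))
        velocities[j] = v
        if abs(v - last_accepted) <= max_jump:
            accepted[j] = True
            last_accepted = v
    return VelocityTrace(times=times[cols], velocities=velocities,
                         accepted=accepted, settings=settings)


def zero_tail(trace: VelocityTrace) -> VelocityTrace:
    """Replace the final two accepted velocities with zero.

    The wave must end at zero velocity; artifacts during deceleration bias
    the tail upward, so anchoring the last two samples at zero pulls the fit
    terminus in.  Idempotent."""
    idx = np.nonzero(trace.accepted)[0]
    if idx.size < 3:
        raise DetectionError("zero_tail requires at least 3 accepted samples")
    v = trace.velocities.copy()
    v[idx[-2:]] = 0.0
    return VelocityTrace(times=trace.times.copy(), velocities=v,
                         accepted=trace.accepted.copy(), settings=trace.settings)


def tangent_shorten(trace: VelocityTrace, first_fit: PDFParameters) -> VelocityTrace:
    """Substitute the 70 %-of-peak tangent for the fitted deceleration limb.

    The tangent to the fitted curve at the time (on the deceleration limb)
    where velocity has fallen to 70 % of peak, extrapolated to the baseline,
    approximates the deceleration line drawn in clinical echocardiography.
    The returned trace resamples the fitted curve on the input trace's time
    grid, follows the tangent from the 70 % point to its baseline intercept
    and is clamped at zero beyond it.  It is intended to be refit; because
    the clinical tangent line reaches the baseline well before the model's
    exponential tail does, the refit deliberately shortens the deceleration
    time (this is a correction toward clinical practice, not a no-op, even
    on clean data).
    """
    t_peak, vmax = peak_characteristics(first_fit)
    dur = ewave_duration(first_fit)
    target = 0.7 * vmax
    if model_velocity(first_fit, dur * (1 - 1e-9)) > target:
        raise DetectionError("deceleration limb never reaches 70% of peak velocity")
    t70 = float(optimize.brentq(
        lambda t: model_velocity(first_fit, t) - target, t_peak, dur))
    h = 1e-7 * max(dur, 1.0)
    slope = (model_velocity(first_fit, t70 + h) - model_velocity(first_fit, t70 - h)) / (2 * h)
    if slope >= 0:
        raise DetectionError("tangent is not decelerating (non-negative slope)")
    t_intercept = t70 + target / (-slope)

    t_rel = trace.times - trace.onset
    v = np.asarray(model_velocity(first_fit, t_rel)).copy()
    on_tangent = t_rel >= t70
    v[on_tangent] = np.maximum(target + slope * (t_rel[on_tangent] - t70), 0.0)
    return VelocityTrace(times=trace.times.copy(), velocities=v,
                         accepted=np.ones_like(t_rel, dtype=bool),
                         settings=trace.settings)


def write_trace(trace: VelocityTrace, path) -> None:
    """Write the accepted samples as 2-column delimited text with header."""
    df = pd.DataFrame({"time_s": trace.accepted_times,
                       "velocity_cm_s": trace.accepted_velocities})
    df.to_csv(path, index=False)


def read_trace(path) -> VelocityTrace:
    """Read a 2-column (time_s, velocity_cm_s) delimited text trace."""
    df = pd.read_csv(Path(path))
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "time_s" not in cols or "velocity_cm_s" not in cols:
        raise DetectionError(
            f"trace file must have columns time_s, velocity_cm_s; found {cols}")
    t = df["time_s"].to_numpy(float)
    v = df["velocity_cm_s"].to_numpy(float)
    return VelocityTrace(times=t, velocities=v,
                         accepted=np.ones_like(t, dtype=bool))
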