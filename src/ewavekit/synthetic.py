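"""Ground-truth synthetic data: velocity traces, spectral-Doppler pixel
strips, multi-beat cines and calibrated DICOM files rendered from known
recoil constants.

The intensity model is phenomenological, not an ultrasound simulation: the
spectral band is filled (bright from the baseline up to the envelope, as a
PW Doppler spectrum appears), speckle is additive clipped Gaussian noise,
and the optional deceleration-phase artifacts sit *above* the envelope —
the failure mode the deceleration-shortening corrections exist for, since
non-E-wave signal during deceleration typically shows higher velocities
than the true wave.  Every generator is a pure function of its spec and
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .envelope import DopplerStrip, VelocityTrace
from .model import PDFParameters, ewave_duration, model_velocity, peak_characteristics

__all__ = [
    "ArtifactSpec",
    "AWaveSpec",
    "SyntheticSpec",
    "StripTruth",
    "CineTruth",
    "synth_trace",
    "synth_strip",
    "synth_cine",
    "synth_dicom",
]

US_SINGLE_FRAME_UID = "1.2.840.10008.5.1.4.1.1.6.1"
US_MULTI_FRAME_UID = "1.2.840.10008.5.1.4.1.1.3.1"


@dataclass(frozen=True)
class ArtifactSpec:
    """Bright non-E-wave signal above the envelope during deceleration.

    ``probability`` is per column inside the window; amplitudes are the extra
    velocity (cm/s) the artifact adds above the true envelope; the window is
    expressed as fractions of the wave duration."""

    probability: float = 0.0
    amplitude: tuple[float, float] = (8.0, 18.0)
    window: tuple[float, float] = (0.45, 1.0)


@dataclass(frozen=True)
class AWaveSpec:
    """Optional late-diastolic (atrial) wave following the E-wave."""

    params: PDFParameters = field(
        default_factory=lambda: PDFParameters(c=20.0, k=160.0, x0=6.0))
    onset_s: float = 0.45


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to render one cardiac cycle of spectral Doppler.

    Geometry defaults emulate a 100 mm/s sweep at a 0.25 mm display pixel
    pitch (2.5 ms per column) with a 0.5 (cm/s)/row velocity scale and the
    baseline near the bottom of a 160-row strip; the default constants are a
    representative normal-range E-wave.  ``noise_sd`` jitters the envelope
    (cm/s); ``background_sd`` controls speckle brightness.
    """

    params: PDFParameters = field(
        default_factory=lambda: PDFParameters(c=17.3, k=135.0, x0=11.4))
    dt_per_col: float = 0.0025
    dv_per_row: float = 0.5
    height: int = 160
    baseline_row: int = 150
    cycle_length_s: float = 0.8
    fill_intensity: tuple[int, int] = (170, 255)
    background_sd: float = 6.0
    noise_sd: float = 0.0
    artifact: ArtifactSpec = field(default_factory=ArtifactSpec)
    a_wave: Optional[AWaveSpec] = None
    flow_sign: int = 1
    seed: int = 0

    @property
    def n_cols(self) -> int:
        return int(round(self.cycle_length_s / self.dt_per_col))


@dataclass
class StripTruth:
    """Exact generating envelope of one rendered beat."""

    params: PDFParameters
    times: np.ndarray        # pixel-centre time of every column, s
    velocities: np.ndarray   # true (pre-quantization) envelope, cm/s
    onset_col: int
    duration_s: float


@dataclass
class CineTruth:
    """Per-beat truths and exact cycle boundaries of a rendered cine."""

    boundaries_cols: list
    beats: list  # StripTruth per beat
    cycle_cols: int


def synth_trace(params: PDFParameters, dt: float = 0.001,
                noise_sd: float = 0.0, seed: int = 0) -> VelocityTrace:
    """Sample the model velocity curve over its duration at step ``dt`` with
    optional Gaussian velocity noise (clipped at zero).  ``noise_sd = 0``
    reproduces the closed form exactly."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    dur = ewave_duration(params)
    t = np.arange(0.0, dur + 0.5 * dt, dt)
    v = np.asarray(model_velocity(params, t), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = np.maximum(v + rng.normal(0.0, noise_sd, size=v.shape), 0.0)
    return VelocityTrace(times=t, velocities=v,
                         accepted=np.ones_like(t, dtype=bool))


def _render_columns(spec: SyntheticSpec, rng: np.random.Generator
                    ) -> tuple[np.ndarray, StripTruth]:
    n_cols = spec.n_cols
    t = (np.arange(n_cols) + 0.5) * spec.dt_per_col
    dur = ewave_duration(spec.params)
    v_true = np.asarray(model_velocity(spec.params, np.minimum(t, dur)))
    v_true = np.where(t <= dur, v_true, 0.0)

    img = np.clip(np.abs(rng.normal(0.0, spec.background_sd,
                                    size=(spec.height, n_cols))), 0, 255)
    v_drawn = v_true.copy()
    if spec.noise_sd > 0:
        v_drawn = np.maximum(
            v_drawn + np.where(t <= dur,
                               rng.normal(0.0, spec.noise_sd, size=n_cols), 0.0),
            0.0)

    lo, hi = spec.fill_intensity
    t_peak, _ = peak_characteristics(spec.params)
    art = spec.artifact
    win_lo, win_hi = art.window[0] * dur, art.window[1] * dur

    def fill(col: int, v_top: float):
        rows_up = int(round(v_top / spec.dv_per_row))
        r_top = max(0, spec.baseline_row - rows_up)
        img[r_top:spec.baseline_row + 1, col] = rng.integers(
            lo, hi + 1, size=spec.baseline_row + 1 - r_top)

    for i in range(n_cols):
        if t[i] <= dur and v_drawn[i] > 0:
            fill(i, v_drawn[i])
        if (art.probability > 0 and win_lo <= t[i] <= win_hi and t[i] > t_peak
                and rng.random() < art.probability):
            fill(i, v_drawn[i] + rng.uniform(*art.amplitude))
        if spec.a_wave is not None:
            ta = t[i] - spec.a_wave.onset_s
            if 0 <= ta <= ewave_duration(spec.a_wave.params):
                va = float(model_velocity(spec.a_wave.params, ta))
                if va > 0:
                    fill(i, va)

    truth = StripTruth(params=spec.params, times=t, velocities=v_true,
                       onset_col=0, duration_s=dur)
    return img.astype(np.uint8), truth


def synth_strip(spec: SyntheticSpec) -> tuple[DopplerStrip, StripTruth]:
    """Render one beat as a calibrated Doppler strip plus its exact truth.

    The envelope row of column ``i`` is the rounded velocity of the model at
    the pixel-centre time, so detection on a noise-free strip can recover the
    envelope to within one row of velocity quantization."""
    vmax = peak_characteristics(spec.params)[1]
    need = vmax + (spec.artifact.amplitude[1] if spec.artifact.probability else 0)
    if need / spec.dv_per_row > spec.baseline_row:
        raise ValueError(
            f"envelope ({need:.0f} cm/s) exceeds the image height; "
            "decrease dv_per_row or raise the image")
    rng = np.random.default_rng(spec.seed)
    img, truth = _render_columns(spec, rng)
    strip = DopplerStrip(pixels=img, dt_per_col=spec.dt_per_col,
                         dv_per_row=spec.dv_per_row,
                         baseline_row=spec.baseline_row, flow_sign=1,
                         source_id=f"synthetic(seed={spec.seed})",
                         heart_rate=60.0 / spec.cycle_length_s)
    if spec.flow_sign == -1:
        strip = DopplerStrip(pixels=img[::-1].copy(),
                             dt_per_col=spec.dt_per_col,
                             dv_per_row=spec.dv_per_row,
                             baseline_row=spec.height - 1 - spec.baseline_row,
                             flow_sign=-1, source_id=strip.source_id,
                             heart_rate=strip.heart_rate)
    return strip, truth


def synth_cine(specs: Sequence[SyntheticSpec]) -> tuple[DopplerStrip, CineTruth]:
    """Concatenate beats into one long strip (a cine recording).

    All specs must share geometry; per-beat constants may differ, e.g. a
    load (x0) ramp for testing the load-independent index."""
    if not specs:
        raise ValueError("need at least one beat spec")
    g = specs[0]
    imgs, truths, boundaries = [], [], []
    col = 0
    for i, spec in enumerate(specs):
        if (spec.dt_per_col, spec.dv_per_row, spec.height,
                spec.baseline_row) != (g.dt_per_col, g.dv_per_row,
                                       g.height, g.baseline_row):
            raise ValueError("all beats in a cine must share geometry")
        strip, truth = synth_strip(replace(spec, flow_sign=1,
                                           seed=spec.seed + i * 7919))
        boundaries.append(col)
        truth.onset_col = col
        imgs.append(strip.pixels)
        truths.append(truth)
        col += strip.n_cols
    pixels = np.hstack(imgs)
    cine = DopplerStrip(pixels=pixels, dt_per_col=g.dt_per_col,
                        dv_per_row=g.dv_per_row, baseline_row=g.baseline_row,
                        flow_sign=1, source_id="synthetic-cine",
                        heart_rate=60.0 / g.cycle_length_s)
    return cine, CineTruth(boundaries_cols=boundaries, beats=truths,
                           cycle_cols=g.n_cols)


def _region_item(spec: SyntheticSpec, x0: int, y0: int, x1: int, y1: int,
                 omit: Sequence[str]) -> Dataset:
    r = Dataset()
    r.RegionSpatialFormat = 3       # spectral
    r.RegionDataType = 3            # PW spectral Doppler
    r.RegionFlags = 0
    r.RegionLocationMinX0 = x0
    r.RegionLocationMinY0 = y0
    r.RegionLocationMaxX1 = x1
    r.RegionLocationMaxY1 = y1
    r.ReferencePixelX0 = 0
    r.ReferencePixelY0 = spec.baseline_row
    r.PhysicalUnitsXDirection = 4   # seconds
    r.PhysicalUnitsYDirection = 7   # cm/s
    r.PhysicalDeltaX = spec.dt_per_col
    r.PhysicalDeltaY = -spec.dv_per_row if spec.flow_sign == 1 else spec.dv_per_row
    for name in omit:
        if hasattr(r, name):
            delattr(r, name)
    return r


def synth_dicom(spec: SyntheticSpec, path, n_frames: int = 1,
                params_per_frame: Optional[Sequence[PDFParameters]] = None,
                omit: Sequence[str] = (), margin: tuple[int, int] = (12, 8),
                add_tissue_region: bool = True):
    """Write a standards-conformant ultrasound DICOM with a calibrated
    spectral-Doppler region rendered from known constants.

    One frame per beat; ``params_per_frame`` overrides the constants beat by
    beat.  The Doppler region is embedded with a margin inside a larger
    canvas so region cropping is exercised on read.  ``omit`` removes region
    attributes (for error-path tests).  Returns the per-frame truths.
    """
    top, left = margin
    truths = []
    frames = []
    for f in range(n_frames):
        p = params_per_frame[f] if params_per_frame else spec.params
        fspec = replace(spec, params=p, flow_sign=1, seed=spec.seed + f * 104729)
        strip, truth = synth_strip(fspec)
        canvas = np.zeros((strip.n_rows + top + 4, strip.n_cols + left + 4),
                          dtype=np.uint8)
        canvas[top:top + strip.n_rows, left:left + strip.n_cols] = strip.pixels
        frames.append(canvas)
        truths.append(truth)
    arr = np.stack(frames)
    rows, cols = arr.shape[1:]

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = (US_MULTI_FRAME_UID if n_frames > 1
                                    else US_SINGLE_FRAME_UID)
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.Manufacturer = "ewavekit synthetic"
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = "SYN000"
    ds.HeartRate = int(round(60.0 / spec.cycle_length_s))
    ds.Rows = rows
    ds.Columns = cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    if n_frames > 1:
        ds.NumberOfFrames = n_frames
    ds.PixelData = arr.tobytes()

    regions = []
    if add_tissue_region:
        tissue = Dataset()
        tissue.RegionSpatialFormat = 1
        tissue.RegionDataType = 1   # tissue, must be ignored by the reader
        tissue.RegionFlags = 0
        tissue.RegionLocationMinX0 = 0
        tissue.RegionLocationMinY0 = 0
        tissue.RegionLocationMaxX1 = cols - 1
        tissue.RegionLocationMaxY1 = top - 1
        regions.append(tissue)
    h, w = frames[0].shape[0] - top - 4, frames[0].shape[1] - left - 4
    regions.append(_region_item(spec, left, top, left + w - 1, top + h - 1, omit))
    ds.SequenceOfUltrasoundRegions = regions
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
    return truths
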