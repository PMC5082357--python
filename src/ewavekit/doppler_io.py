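"""DICOM reading with ultrasound-region calibration, cine splitting,
session persistence and result export.

A spectral-Doppler DICOM carries its physical calibration in the
SequenceOfUltrasoundRegions: each region names its pixel bounds, the
physical delta per column (seconds) and per row (cm/s), and the baseline
(reference) row.  The reader locates the spectral region, crops the pixel
matrix to it and maps the calibration into a :class:`DopplerStrip`; cine
recordings spanning several cardiac cycles are split on onset-aligned
cycle boundaries.  Sessions are persisted in an open JSON container rather
than any proprietary workspace format.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pydicom

from . import __version__
from .envelope import DetectionSettings, DopplerStrip, VelocityTrace
from .errors import (
    DicomRegionError,
    EwaveError,
    MissingCalibrationError,
    SessionVersionError,
)
from .fitting import PDFModel, PDFResults
from .model import LoadIndependentIndex, PDFParameters, load_independence

__all__ = [
    "DicomDopplerSource",
    "StudyResult",
    "read_doppler_dicom",
    "read_doppler_folder",
    "split_cine",
    "export_results",
    "append_study_database",
    "save_session",
    "load_session",
]

SESSION_SCHEMA = "ewavekit-session"
SESSION_VERSION = 1

_BEAT_COLUMNS = [
    "c", "k", "x0", "vmax_cm_s", "at_s", "edec_ms", "duration_s", "vti_cm",
    "kx0_mN", "cvmax_mN", "energy_mJ", "beta", "kfei_pct", "tau_ms",
]


@dataclass
class DicomDopplerSource:
    """Provenance and calibration of one DICOM Doppler source."""

    path: str
    vendor: str
    region_bounds: tuple  # (x0, y0, x1, y1) inclusive pixel bounds
    dt_per_col: float
    dv_per_row: float
    baseline_row: int
    n_frames: int
    heart_rate: Optional[float] = None
    anonymized: bool = False


def _spectral_region(ds) -> "pydicom.Dataset":
    regions = getattr(ds, "SequenceOfUltrasoundRegions", None)
    if not regions:
        raise DicomRegionError("no ultrasound regions in file")
    spectral = [r for r in regions if int(getattr(r, "RegionDataType", 0)) in (3, 4)]
    if not spectral:
        raise DicomRegionError("no Doppler region (no spectral RegionDataType)")
    # several spectral regions: the largest area wins
    def area(r):
        return ((int(r.RegionLocationMaxX1) - int(r.RegionLocationMinX0) + 1)
                * (int(r.RegionLocationMaxY1) - int(r.RegionLocationMinY0) + 1))
    return max(spectral, key=area)


def read_doppler_dicom(path) -> tuple[list[DopplerStrip], DicomDopplerSource]:
    """Read a single- or multi-frame ultrasound DICOM into calibrated strips.

    The spectral-Doppler region is located through the region metadata, the
    pixels are cropped to it, and its physical deltas become the strip
    calibration.  Multi-frame (cine) files yield one strip per frame with
    consecutive time offsets.  Missing calibration raises an error naming
    the absent attribute; sub-recommended sweep speeds only warn.
    """
    path = Path(path)
    ds = pydicom.dcmread(str(path))
    region = _spectral_region(ds)
    for attr in ("RegionLocationMinX0", "RegionLocationMinY0",
                 "RegionLocationMaxX1", "RegionLocationMaxY1",
                 "PhysicalDeltaX", "PhysicalDeltaY", "ReferencePixelY0"):
        if getattr(region, attr, None) is None:
            raise MissingCalibrationError(attr)
    ux = getattr(region, "PhysicalUnitsXDirection", 4)
    uy = getattr(region, "PhysicalUnitsYDirection", 7)
    if int(ux) != 4 or int(uy) != 7:
        raise DicomRegionError(
            f"unsupported region units (X={ux}, Y={uy}); expected seconds × cm/s")
    dt = float(region.PhysicalDeltaX)
    dy = float(region.PhysicalDeltaY)
    if dt <= 0 or dy == 0:
        raise MissingCalibrationError("PhysicalDeltaX/PhysicalDeltaY")
    x0, y0 = int(region.RegionLocationMinX0), int(region.RegionLocationMinY0)
    x1, y1 = int(region.RegionLocationMaxX1), int(region.RegionLocationMaxY1)
    baseline = int(region.ReferencePixelY0)  # relative to the region top
    flow_sign = 1 if dy < 0 else -1

    arr = ds.pixel_array
    if arr.ndim == 2:
        arr = arr[None]
    n_frames = arr.shape[0]
    heart_rate = float(ds.HeartRate) if getattr(ds, "HeartRate", None) else None
    frame_len_s = (x1 - x0 + 1) * dt

    strips = []
    for f in range(n_frames):
        crop = arr[f, y0:y1 + 1, x0:x1 + 1]
        strip = DopplerStrip(pixels=crop, dt_per_col=dt, dv_per_row=abs(dy),
                             baseline_row=baseline, flow_sign=flow_sign,
                             source_id=f"{path.name}#frame{f}",
                             offset_s=f * frame_len_s, heart_rate=heart_rate)
        msg = strip.sweep_speed_warning()
        if msg:
            warnings.warn(msg)
        strips.append(strip)

    source = DicomDopplerSource(
        path=str(path), vendor=str(getattr(ds, "Manufacturer", "")),
        region_bounds=(x0, y0, x1, y1), dt_per_col=dt, dv_per_row=abs(dy),
        baseline_row=baseline, n_frames=n_frames, heart_rate=heart_rate,
        anonymized=not str(getattr(ds, "PatientID", "")),
    )
    return strips, source


def read_doppler_folder(folder) -> list[tuple[list[DopplerStrip], DicomDopplerSource]]:
    """Read every DICOM in a folder; mixed single-frame and cine content is
    rejected with a clear message."""
    folder = Path(folder)
    paths = sorted(p for p in folder.iterdir() if p.suffix.lower() == ".dcm")
    if not paths:
        raise EwaveError(f"no DICOM files in {folder}")
    loaded = [read_doppler_dicom(p) for p in paths]
    kinds = {src.n_frames > 1 for _, src in loaded}
    if len(kinds) > 1:
        raise EwaveError(
            "folder mixes single-frame and cine DICOM files; "
            "load them separately")
    return loaded


def _estimate_period_cols(strip: DopplerStrip) -> Optional[int]:
    """Cycle length in columns from the autocorrelation of column sums."""
    x = strip.pixels[: strip.baseline_row + 1].astype(float).sum(axis=0)
    x = x - x.mean()
    n = x.size
    ac = np.correlate(x, x, mode="full")[n - 1:]
    lo = max(2, int(0.3 / strip.dt_per_col))
    hi = min(n - 1, int(2.0 / strip.dt_per_col))
    if hi <= lo or ac[0] <= 0:
        return None
    lag = lo + int(np.argmax(ac[lo:hi + 1]))
    if ac[lag] < 0.2 * ac[0]:
        return None
    return int(lag)


def split_cine(strip: DopplerStrip, method: str = "auto") -> list[DopplerStrip]:
    """Split a long recording into one strip per cardiac cycle.

    The period comes from heart-rate metadata when available (``method``
    "auto" or "metadata") with an autocorrelation fallback over the column
    intensity sums; boundaries are aligned to the first flow onset.  When no
    periodicity is found, the strip is returned whole with a warning.
    """
    period = None
    if method in ("auto", "metadata") and strip.heart_rate:
        period = int(round(60.0 / strip.heart_rate / strip.dt_per_col))
    if period is None and method in ("auto", "autocorrelation"):
        period = _estimate_period_cols(strip)
    if period is None or strip.n_cols < 1.3 * period:
        if strip.n_cols >= 2 and period is None:
            warnings.warn("no periodicity found; returning the strip uncut")
        return [strip]

    # onset alignment: first column whose intensity sum rises clearly above
    # the background floor
    sums = strip.pixels[: strip.baseline_row + 1].astype(float).sum(axis=0)
    smooth = np.convolve(sums, np.ones(3) / 3.0, mode="same")
    floor = smooth.min() + 0.05 * (smooth.max() - smooth.min())
    above = np.nonzero(smooth > floor)[0]
    offset = int(above[0]) if above.size else 0
    if offset > period // 2:  # onset of a truncated leading beat
        offset = 0

    out = []
    start = offset
    while start + period <= strip.n_cols + period // 4:
        end = min(start + period, strip.n_cols)
        if end - start < period // 2:
            break
        out.append(DopplerStrip(
            pixels=strip.pixels[:, start:end].copy(),
            dt_per_col=strip.dt_per_col, dv_per_row=strip.dv_per_row,
            baseline_row=strip.baseline_row, flow_sign=strip.flow_sign,
            source_id=f"{strip.source_id}[cycle@{start}]",
            offset_s=strip.offset_s + start * strip.dt_per_col,
            heart_rate=strip.heart_rate))
        start += period
    return out if out else [strip]


# ---------------------------------------------------------------------------
# study results, export, session persistence
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Per-case container: per-beat fits, summaries, M/B and provenance."""

    case_id: str
    fits: list  # PDFResults, beat order
    strips: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))
    anonymized: bool = False

    def beat_frame(self) -> pd.DataFrame:
        rows = []
        for i, fit in enumerate(self.fits, start=1):
            idx = fit.indices
            p = fit.params
            rows.append({
                "beat": i, "c": p.c, "k": p.k, "x0": p.x0,
                "vmax_cm_s": idx.vmax, "at_s": idx.at, "edec_ms": idx.edec,
                "duration_s": idx.duration, "vti_cm": idx.vti,
                "kx0_mN": idx.kx0, "cvmax_mN": idx.cvmax,
                "energy_mJ": idx.energy, "beta": idx.beta,
                "kfei_pct": idx.kfei, "tau_ms": idx.tau,
                "residual_norm": fit.residual_norm, "method": fit.method,
                "converged": fit.converged,
            })
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        beats = self.beat_frame()
        mean = beats[_BEAT_COLUMNS].mean()
        sd = beats[_BEAT_COLUMNS].std(ddof=1)
        return pd.DataFrame({"mean": mean, "sd": sd}).T

    def load_index(self) -> Optional[LoadIndependentIndex]:
        """M and B across beats; None when undefined (< 2 beats or no
        variation in resistive force)."""
        try:
            return load_independence(self.fits)
        except ValueError:
            return None


def export_results(study: StudyResult, path, fmt: str = "csv",
                   append_db: Optional[str] = None,
                   anonymize: bool = False) -> pd.DataFrame:
    """Write one row per beat plus a mean/SD summary block and M/B.

    CSV dialect: UTF-8, comma, header row, '.' decimal (TSV swaps the
    separator; XLSX goes through openpyxl).  Numbers are written at full
    float precision, so a reread equals the in-memory values.  With
    ``anonymize`` the export carries no case id, source path or timestamp.
    Returns the exported table.
    """
    if not study.fits:
        raise EwaveError("nothing to export: study has no fits")
    beats = study.beat_frame()
    beats.insert(0, "record", beats.pop("beat").astype(str))
    summary = study.summary_frame()
    li = study.load_index()
    summary_rows = []
    for name in ("mean", "sd"):
        row = {"record": name}
        row.update(summary.loc[name].to_dict())
        summary_rows.append(row)
    if li is not None:
        summary_rows[0]["m_slope"] = li.m
        summary_rows[0]["b_intercept_mN"] = li.b
    table = pd.concat([beats, pd.DataFrame(summary_rows)], ignore_index=True)
    if not anonymize:
        table.insert(1, "case_id", study.case_id)
        table["source"] = ";".join(
            s.source_id for s in study.strips) or study.provenance.get("source", "")
        table["exported"] = study.created
    table["software"] = f"ewavekit {__version__}"

    path = Path(path)
    if fmt == "csv":
        table.to_csv(path, index=False, encoding="utf-8")
    elif fmt == "tsv":
        table.to_csv(path, index=False, sep="\t", encoding="utf-8")
    elif fmt == "xlsx":
        table.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")

    if append_db is not None:
        append_study_database(study, append_db, anonymize=anonymize)
    return table


def append_study_database(study: StudyResult, db_path,
                          anonymize: bool = False) -> pd.DataFrame:
    """Append this case's summary (means, SDs, M, B) to a cumulative
    study-database CSV; a header mismatch is an error, never silent drift."""
    summary = study.summary_frame()
    li = study.load_index()
    row = {"case_id": "anonymous" if anonymize else study.case_id,
           "n_beats": len(study.fits)}
    for col in _BEAT_COLUMNS:
        row[f"{col}_mean"] = summary.loc["mean", col]
        row[f"{col}_sd"] = summary.loc["sd", col]
    row["m_slope"] = li.m if li else np.nan
    row["b_intercept_mN"] = li.b if li else np.nan
    new = pd.DataFrame([row])

    db_path = Path(db_path)
    if db_path.exists():
        existing = pd.read_csv(db_path)
        if list(existing.columns) != list(new.columns):
            raise EwaveError(
                f"study database {db_path} has a different schema; refusing to append")
        out = pd.concat([existing, new], ignore_index=True)
    else:
        out = new
    out.to_csv(db_path, index=False, encoding="utf-8")
    return out


def _trace_to_json(trace: VelocityTrace) -> dict:
    d = {"times": trace.times.tolist(),
         "velocities": [None if np.isnan(v) else v for v in trace.velocities],
         "accepted": trace.accepted.astype(int).tolist()}
    if trace.settings is not None:
        s = trace.settings
        d["settings"] = {"t_start": s.t_start, "t_end": s.t_end,
                         "threshold": s.threshold, "max_jump": s.max_jump,
                         "zero_tail": s.zero_tail,
                         "tangent_shorten": s.tangent_shorten}
    return d


def _trace_from_json(d: dict) -> VelocityTrace:
    settings = None
    if "settings" in d:
        settings = DetectionSettings(**d["settings"])
    v = np.array([np.nan if x is None else x for x in d["velocities"]], float)
    return VelocityTrace(times=np.asarray(d["times"], float), velocities=v,
                         accepted=np.asarray(d["accepted"], bool),
                         settings=settings)


def _strip_to_json(strip: DopplerStrip, anonymize: bool) -> dict:
    return {"pixels": strip.pixels.astype(int).tolist(),
            "dt_per_col": strip.dt_per_col, "dv_per_row": strip.dv_per_row,
            "baseline_row": strip.baseline_row, "flow_sign": strip.flow_sign,
            "source_id": "" if anonymize else strip.source_id,
            "offset_s": strip.offset_s, "heart_rate": strip.heart_rate}


def save_session(study: StudyResult, path, anonymize: bool = False) -> None:
    """Persist strips, traces, settings and fits losslessly as JSON.

    The container is self-describing (schema name + version); with
    ``anonymize`` the case id, provenance and source identifiers are
    stripped before writing."""
    doc = {
        "schema": SESSION_SCHEMA,
        "version": SESSION_VERSION,
        "case_id": "anonymous" if anonymize else study.case_id,
        "anonymized": anonymize or study.anonymized,
        "provenance": {} if anonymize else study.provenance,
        "created": study.created,
        "beats": [
            {"params": {"c": f.params.c, "k": f.params.k, "x0": f.params.x0},
             "method": f.method, "converged": f.converged,
             "residual_norm": f.residual_norm, "nfev": f.nfev,
             "trace": _trace_to_json(f.trace)}
            for f in study.fits
        ],
        "strips": [_strip_to_json(s, anonymize) for s in study.strips],
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_session(path) -> StudyResult:
    """Load a session container back into a :class:`StudyResult`.

    Truncated or non-JSON files raise a parse error; a schema version this
    build does not understand raises :class:`SessionVersionError`."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != SESSION_SCHEMA:
        raise SessionVersionError(f"not an {SESSION_SCHEMA} container")
    if doc.get("version") != SESSION_VERSION:
        raise SessionVersionError(
            f"session version {doc.get('version')} needs migration; "
            f"this build reads version {SESSION_VERSION}")
    fits = []
    for beat in doc["beats"]:
        trace = _trace_from_json(beat["trace"])
        model = PDFModel(trace)
        res = PDFResults(model, PDFParameters(**beat["params"]),
                         residual_norm=beat["residual_norm"],
                         converged=beat["converged"], method=beat["method"],
                         nfev=beat.get("nfev", 0))
        fits.append(res)
    strips = [DopplerStrip(pixels=np.asarray(s["pixels"], dtype=np.uint8),
                           dt_per_col=s["dt_per_col"],
                           dv_per_row=s["dv_per_row"],
                           baseline_row=s["baseline_row"],
                           flow_sign=s["flow_sign"], source_id=s["source_id"],
                           offset_s=s.get("offset_s", 0.0),
                           heart_rate=s.get("heart_rate"))
              for s in doc.get("strips", [])]
    return StudyResult(case_id=doc["case_id"], fits=fits, strips=strips,
                       provenance=doc.get("provenance", {}),
                       created=doc.get("created", ""),
                       anonymized=doc.get("anonymized", False))
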