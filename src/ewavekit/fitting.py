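"""Nonlinear least-squares estimation of the recoil constants from a
detected velocity trace, and the semi-automatic multi-beat fitting loop.

The central objects follow the Model/Results convention of statistical
modelling packages: :class:`PDFModel` is built from a
:class:`~ewavekit.envelope.VelocityTrace` (or a DataFrame) and its
:meth:`~PDFModel.fit` returns a :class:`PDFResults` carrying the estimated
constants, their standard errors, diagnostics and a ``summary()`` table.
The functional entry points ``fit_pdf`` and ``fit_with_shortening`` are thin
wrappers over these objects.

The optimizer is Levenberg–Marquardt on a smooth reparameterization
(softplus for c ≥ 0, log for k > 0 and x0 > 0) so the physical bounds are
enforced without constrained solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from skimage.feature import match_template

from . import envelope as env
from .errors import DetectionError, FitError, NoMatchError
from .model import (
    DerivedIndices,
    PDFParameters,
    Triad,
    derived_indices,
    model_velocity,
    params_from_triad,
)

__all__ = [
    "PDFModel",
    "PDFResults",
    "FitResult",
    "Template",
    "AutofitOptions",
    "AutoFitReport",
    "fit_pdf",
    "fit_with_shortening",
    "build_start_template",
    "locate_start",
    "autofit_sequence",
    "empirical_triad",
]

_MIN_SAMPLES = 5


def _softplus(a: float | np.ndarray):
    return np.logaddexp(0.0, a)


def _softplus_inv(c: float) -> float:
    # inverse of log(1 + e^a); guard the c -> 0 boundary
    c = max(c, 1e-8)
    return c + math.log(-math.expm1(-c)) if c < 30 else c


def _theta_to_params(theta: np.ndarray) -> PDFParameters:
    a, logk, logx0 = theta
    return PDFParameters(c=float(_softplus(a)), k=float(np.exp(logk)),
                         x0=float(np.exp(logx0)))


def _params_to_theta(p: PDFParameters) -> np.ndarray:
    return np.array([_softplus_inv(p.c), math.log(p.k), math.log(p.x0)])


def empirical_triad(trace: env.VelocityTrace) -> Triad:
    """Crude (at, dt, vmax) read straight off the accepted samples, used to
    seed the optimizer via the closed-form triad inversion."""
    t = trace.relative_times()
    v = trace.accepted_velocities
    i_peak = int(np.argmax(v))
    vmax = float(v[i_peak])
    at = float(t[i_peak])
    dt = float(t[-1] - t[i_peak])
    if at <= 0:
        at = max(float(t[1]), 1e-3)
    if dt <= 0:
        dt = at
    return Triad(at=at, dt=dt, vmax=max(vmax, 1e-3))


def _initial_params(trace: env.VelocityTrace) -> PDFParameters:
    triad = empirical_triad(trace)
    if triad.at <= triad.dt:
        try:
            return params_from_triad(triad)
        except Exception:
            pass
    # fallback: symmetric undamped wave with the observed rise time
    half_period = 2.0 * triad.at
    k = (math.pi / half_period) ** 2
    return PDFParameters(c=1.0, k=k, x0=triad.vmax / math.sqrt(k))


class PDFModel:
    """Damped-recoil (PDF) model of one E-wave, ready to fit.

    Parameters
    ----------
    trace : VelocityTrace
        Detected envelope; only accepted samples enter the fit, with times
        re-referenced so flow onset is t = 0.
    """

    def __init__(self, trace: env.VelocityTrace):
        if trace.n_accepted < _MIN_SAMPLES:
            raise FitError(
                f"need at least {_MIN_SAMPLES} accepted samples, "
                f"got {trace.n_accepted}")
        self.trace = trace
        self.t = trace.relative_times()
        self.v = trace.accepted_velocities
        self.nobs = len(self.t)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time_s",
                       velocity_col: str = "velocity_cm_s") -> "PDFModel":
        t = df[time_col].to_numpy(float)
        v = df[velocity_col].to_numpy(float)
        trace = env.VelocityTrace(times=t, velocities=v,
                                  accepted=np.ones_like(t, dtype=bool))
        return cls(trace)

    @classmethod
    def from_arrays(cls, times, velocities) -> "PDFModel":
        times = np.asarray(times, float)
        return cls(env.VelocityTrace(times=times,
                                     velocities=np.asarray(velocities, float),
                                     accepted=np.ones_like(times, dtype=bool)))

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        try:
            p = _theta_to_params(theta)
        except Exception:
            return np.full(self.nobs, 1e6)
        return np.asarray(model_velocity(p, self.t)) - self.v

    def fit(self, init: Optional[PDFParameters] = None,
            method: str = "full-fit", **lsq_kwargs) -> "PDFResults":
        """Estimate (c, k, x0) by Levenberg–Marquardt least squares.

        ``init`` defaults to the closed-form triad inversion of the trace's
        empirical acceleration/deceleration times and peak velocity.  With
        ``method="triad"`` no optimization is run: the closed-form inversion
        itself is the estimate (the program's alternative to curve fitting).
        """
        start = init if init is not None else _initial_params(self.trace)
        if method == "triad":
            resid = np.asarray(model_velocity(start, self.t)) - self.v
            return PDFResults(self, start, residual_norm=float(np.linalg.norm(resid)),
                              converged=True, method="triad", nfev=0)
        theta0 = _params_to_theta(start)
        sol = optimize.least_squares(self._residuals, theta0, method="lm",
                                     xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                     max_nfev=2000, **lsq_kwargs)
        params = _theta_to_params(sol.x)
        return PDFResults(self, params,
                          residual_norm=float(np.linalg.norm(sol.fun)),
                          converged=bool(sol.success), method="full-fit",
                          nfev=int(sol.nfev))


class PDFResults:
    """Fit results: estimated constants, uncertainties and diagnostics.

    Standard errors come from the Gauss–Newton covariance
    σ̂²·(JᵀJ)⁻¹ evaluated at the optimum in the physical (c, k, x0)
    coordinates; they are NaN when the Jacobian is rank deficient (e.g. a
    fit pinned at the c = 0 boundary).
    """

    param_names = ("c", "k", "x0")

    def __init__(self, model: PDFModel, params: PDFParameters, *,
                 residual_norm: float, converged: bool, method: str, nfev: int):
        self.model = model
        self.params = params
        self.residual_norm = residual_norm
        self.converged = converged
        self.method = method
        self.nfev = nfev
        self.stages: list[str] = []
        self._indices: Optional[DerivedIndices] = None
        self._bse: Optional[dict] = None

    # -- statsmodels-flavoured surface -------------------------------------
    @property
    def trace(self) -> env.VelocityTrace:
        return self.model.trace

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(model_velocity(self.params, self.model.t))

    @property
    def resid(self) -> np.ndarray:
        return self.fittedvalues - self.model.v

    @property
    def indices(self) -> DerivedIndices:
        if self._indices is None:
            self._indices = derived_indices(self.params)
        return self._indices

    @property
    def bse(self) -> dict:
        if self._bse is None:
            self._bse = self._compute_bse()
        return self._bse

    def _compute_bse(self) -> dict:
        p = np.array(self.params.as_tuple())
        t = self.model.t
        J = np.empty((self.nobs, 3))
        for j in range(3):
            h = 1e-6 * max(abs(p[j]), 1e-3)
            lo = p.copy(); hi = p.copy()
            hi[j] += h
            lo[j] = max(lo[j] - h, 1e-12 if j > 0 else 0.0)
            try:
                v_hi = model_velocity(PDFParameters(*hi), t)
                v_lo = model_velocity(PDFParameters(*lo), t)
            except Exception:
                return dict(zip(self.param_names, [np.nan] * 3))
            J[:, j] = (np.asarray(v_hi) - np.asarray(v_lo)) / (hi[j] - lo[j])
        dof = max(self.nobs - 3, 1)
        s2 = self.residual_norm**2 / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        return dict(zip(self.param_names, se))

    def predict(self, t) -> np.ndarray:
        """Model velocity at onset-relative times ``t`` (s)."""
        return np.asarray(model_velocity(self.params, np.asarray(t, float)))

    def plot(self, ax=None):
        """Overlay the fitted curve on the detected samples."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tr = self.model
        ax.plot(tr.t, tr.v, ".", label="detected", ms=4)
        tt = np.linspace(0, self.indices.duration, 200)
        ax.plot(tt, self.predict(tt), "-", label="fitted")
        ax.set_xlabel("time since onset (s)")
        ax.set_ylabel("velocity (cm/s)")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Plain-text summary table of constants and derived indices."""
        b = self.bse
        idx = self.indices
        lines = [
            "Damped-recoil (PDF) E-wave fit",
            "=" * 46,
            f"method: {self.method}   converged: {self.converged}   "
            f"n={self.nobs}   ||resid||={self.residual_norm:.4g} cm/s",
            "-" * 46,
            f"{'param':>6} {'estimate':>12} {'std err':>10}  unit",
            f"{'c':>6} {self.params.c:>12.4g} {b['c']:>10.3g}  g/s",
            f"{'k':>6} {self.params.k:>12.4g} {b['k']:>10.3g}  g/s^2",
            f"{'x0':>6} {self.params.x0:>12.4g} {b['x0']:>10.3g}  cm",
            "-" * 46,
            f"Vmax  {idx.vmax:8.2f} cm/s   AT    {idx.at*1000:7.1f} ms",
            f"Edec  {idx.edec:8.1f} ms     VTI   {idx.vti:7.2f} cm",
            f"kx0   {idx.kx0:8.2f} mN     cVmax {idx.cvmax:7.2f} mN",
            f"E     {idx.energy:8.3f} mJ     beta  {idx.beta:7.1f} g^2/s^2",
            f"KFEI  {idx.kfei:8.1f} %      tau   {idx.tau:7.1f} ms",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<PDFResults c={self.params.c:.3g} k={self.params.k:.4g} "
                f"x0={self.params.x0:.3g} converged={self.converged}>")


#: alias matching the domain vocabulary
FitResult = PDFResults


def fit_pdf(trace: env.VelocityTrace,
            init: Optional[PDFParameters] = None) -> PDFResults:
    """Fit the recoil constants to a detected trace (see :class:`PDFModel`)."""
    return PDFModel(trace).fit(init=init)


def fit_with_shortening(strip: env.DopplerStrip,
                        settings: env.DetectionSettings) -> PDFResults:
    """Full single-beat pipeline: detect → (zero tail) → fit →
    (tangent shorten + refit), honouring the two shortening flags
    independently.  Stage names are logged on the result."""
    stages = []
    try:
        trace = env.detect_envelope(strip, settings)
        stages.append("detect_envelope")
        if settings.zero_tail:
            trace = env.zero_tail(trace)
            stages.append("zero_tail")
    except DetectionError as e:
        raise DetectionError(f"detection stage failed: {e}") from e
    try:
        result = fit_pdf(trace)
        stages.append("fit_pdf")
        if settings.tangent_shorten:
            shortened = env.tangent_shorten(trace, result.params)
            stages.append("tangent_shorten")
            result = fit_pdf(shortened, init=result.params)
            stages.append("refit")
    except (FitError, DetectionError) as e:
        raise type(e)(f"fitting stage failed after {stages}: {e}") from e
    result.stages = stages
    return result


# ---------------------------------------------------------------------------
# semi-automatic multi-beat analysis
# ---------------------------------------------------------------------------

@dataclass
class Template:
    """Pixel patch around the onset of a user-accepted E-wave, used to locate
    the onset of subsequent beats by normalized cross-correlation."""

    pixels: np.ndarray
    onset_col: int       # onset column in the source strip
    col_start: int       # first column of the patch in the source strip
    row_start: int       # first row of the patch in the source strip
    clipped: bool = False

    @property
    def onset_offset(self) -> int:
        """Onset column relative to the patch's left edge."""
        return self.onset_col - self.col_start


def build_start_template(strip: env.DopplerStrip, fit: PDFResults,
                         half_width: int = 10,
                         height: Optional[int] = None) -> Template:
    """Cut the onset-centred patch used for beat-to-beat onset search.

    The patch spans ``half_width`` columns on each side of the onset column
    and the rows from just below the baseline up to ``height`` rows above it
    (default: half the strip height).  Patches clipped at the strip edge are
    flagged."""
    strip = env.orient_strip(strip)
    onset_col = int(round(fit.trace.onset / strip.dt_per_col))
    if height is None:
        height = strip.n_rows // 2
    row_start = max(0, strip.baseline_row - height)
    row_end = min(strip.n_rows, strip.baseline_row + 2)
    col_start = onset_col - half_width
    col_end = onset_col + half_width + 1
    clipped = col_start < 0 or col_end > strip.n_cols
    col_start = max(0, col_start)
    col_end = min(strip.n_cols, col_end)
    return Template(pixels=strip.pixels[row_start:row_end, col_start:col_end].copy(),
                    onset_col=onset_col, col_start=col_start,
                    row_start=row_start, clipped=clipped)


def locate_start(template: Template, strip: env.DopplerStrip,
                 floor: float = 0.6) -> float:
    """Find the E-wave onset time in a strip by normalized cross-correlation.

    Returns the left-edge time of the matched onset column (flow begins at
    the column boundary, half a pixel before the column's sample time).  A
    peak correlation below ``floor`` raises :class:`NoMatchError`, which the
    multi-beat loop records as a skipped beat."""
    strip = env.orient_strip(strip)
    if (template.pixels.shape[0] > strip.n_rows
            or template.pixels.shape[1] > strip.n_cols):
        raise NoMatchError("template larger than the search strip")
    corr = match_template(strip.pixels.astype(float), template.pixels.astype(float))
    peak = float(corr.max())
    if peak < floor:
        raise NoMatchError(f"best correlation {peak:.3f} below floor {floor:.2f}")
    _, col = np.unravel_index(int(np.argmax(corr)), corr.shape)
    onset_col = int(col) + template.onset_offset
    return onset_col * strip.dt_per_col


@dataclass
class AutofitOptions:
    """Knobs of the semi-automatic loop; defaults are the published rules:
    detection runs from the matched onset to 1/3 of a cardiac cycle or to
    where velocity falls below 35 % of the wave's peak, and a fit whose
    c, k or x0 deviates more than 40 % from the mean of the previously
    accepted beats is discarded."""

    ncc_floor: float = 0.6
    discard_fraction: float = 0.40
    stop_velocity_fraction: float = 0.35
    cycle_fraction: float = 1.0 / 3.0
    cycle_length_s: Optional[float] = None
    detection: env.DetectionSettings = field(default_factory=env.DetectionSettings)


@dataclass
class AutoFitReport:
    """Outcome of the multi-beat loop: every input beat lands exactly once
    in ``fits`` (accepted, beat order) or ``discarded`` (id, reason)."""

    fits: list
    discarded: list  # (beat_index, reason) with reason in
    #                  {"no-template-match", "parameter-deviation", "fit-failure"}
    template_meta: Template
    deviations: list = field(default_factory=list)  # per-beat max relative deviation


def _cycle_length(beats: Sequence[env.DopplerStrip],
                  options: AutofitOptions) -> float:
    if options.cycle_length_s is not None:
        return options.cycle_length_s
    for b in beats:
        if b.heart_rate:
            return 60.0 / b.heart_rate
    return float(np.median([b.duration_s for b in beats]))


def _truncate_at_stop(trace: env.VelocityTrace, stop_fraction: float) -> env.VelocityTrace:
    """Apply the 35 %-of-peak stop rule to an already detected trace."""
    v = trace.accepted_velocities
    i_peak = int(np.argmax(v))
    below = np.nonzero(v[i_peak:] < stop_fraction * v[i_peak])[0]
    if below.size == 0:
        return trace
    t_stop = trace.accepted_times[i_peak + below[0]]
    keep = trace.times <= t_stop
    return env.VelocityTrace(times=trace.times[keep],
                             velocities=trace.velocities[keep],
                             accepted=trace.accepted[keep],
                             settings=trace.settings)


def autofit_sequence(beats: Sequence[env.DopplerStrip], seed_fit: PDFResults,
                     options: Optional[AutofitOptions] = None) -> AutoFitReport:
    """Semi-automatic fitting of a beat sequence from one accepted seed fit.

    ``beats[0]`` is the seed beat the user fitted manually (``seed_fit``);
    for each subsequent beat the onset is located by template matching, the
    envelope detected under the stop rules, fitted, and the fit accepted
    only if every constant stays within ``discard_fraction`` of the running
    mean of previously accepted beats (seed included).
    """
    if options is None:
        options = AutofitOptions()
    template = build_start_template(beats[0], seed_fit)
    cycle = _cycle_length(beats, options)
    accepted_params = [np.array(seed_fit.params.as_tuple())]
    fits: list = [seed_fit]
    discarded: list = []
    deviations: list = [0.0]

    for i, beat in enumerate(beats[1:], start=1):
        try:
            onset = locate_start(template, beat, floor=options.ncc_floor)
        except NoMatchError:
            discarded.append((i, "no-template-match"))
            deviations.append(np.nan)
            continue
        det = replace(options.detection,
                      t_start=onset,
                      t_end=min(onset + cycle * options.cycle_fraction,
                                beat.duration_s))
        try:
            trace = env.detect_envelope(beat, det)
            trace = _truncate_at_stop(trace, options.stop_velocity_fraction)
            if det.zero_tail:
                trace = env.zero_tail(trace)
            result = fit_pdf(trace)
            if det.tangent_shorten:
                shortened = env.tangent_shorten(trace, result.params)
                result = fit_pdf(shortened, init=result.params)
            if not result.converged:
                raise FitError("optimizer did not converge")
        except (DetectionError, FitError):
            discarded.append((i, "fit-failure"))
            deviations.append(np.nan)
            continue
        mean = np.mean(accepted_params, axis=0)
        dev = np.abs(np.array(result.params.as_tuple()) - mean) / np.abs(mean)
        deviations.append(float(dev.max()))
        if np.any(dev > options.discard_fraction):
            discarded.append((i, "parameter-deviation"))
            continue
        accepted_params.append(np.array(result.params.as_tuple()))
        fits.append(result)

    return AutoFitReport(fits=fits, discarded=discarded,
                         template_meta=template, deviations=deviations)
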