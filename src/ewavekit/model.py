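"""Kinematic (PDF) model of early diastolic transmitral filling.

Early left-ventricular filling is modelled as the recoil of a damped, loaded
spring: a mass ``m`` (fixed at 1 g by convention) displaced by ``x0`` cm and
released from rest obeys

    m·ẍ + c·ẋ + k·x = 0,     x(0) = x0,  ẋ(0) = 0,

where ``k`` (g/s²) is chamber stiffness, ``c`` (g/s) viscoelastic damping and
``x0`` (cm) the load.  The transmitral velocity envelope of the E-wave is the
speed ``|ẋ(t)|`` of this recoil.  This module provides the forward velocity
curve, its closed-form characteristics (peak, duration, velocity–time
integral), the physiological indices derived from the constants, the
equivalent (acceleration time, deceleration time, peak velocity) triad
parameterization and its inversion, and the load-independent index M/B
obtained from beats acquired under varying load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate, optimize, stats

from .errors import InvalidParametersError, NonPhysicalTriadError

__all__ = [
    "PDFParameters",
    "DerivedIndices",
    "Triad",
    "LoadIndependentIndex",
    "model_velocity",
    "peak_characteristics",
    "ewave_duration",
    "velocity_time_integral",
    "kinematic_filling_efficiency",
    "derived_indices",
    "tau_estimate",
    "triad_from_params",
    "params_from_triad",
    "load_independence",
]

# Relative tolerance on the discriminant c² − 4k below which the motion is
# treated as critically damped (both closed forms agree to machine precision
# well outside this band).
_CRITICAL_RTOL = 1e-9

# Unit conversions from CGS (g, cm, s) to the reporting units.
DYN_TO_MN = 0.01  # 1 dyn = 1 g·cm/s² = 0.01 mN
ERG_TO_MJ = 1e-4  # 1 erg = 1 g·cm²/s² = 1e-4 mJ


@dataclass(frozen=True)
class PDFParameters:
    """The three constants of the damped-recoil filling model.

    Attributes
    ----------
    c : float
        Viscoelastic damping constant, g/s.  ``c >= 0``.
    k : float
        Stiffness constant, g/s² (inertial mass fixed at 1 g, so ``k`` has
        the dimension of an angular frequency squared).  ``k > 0``.
    x0 : float
        Load: effective myocardial displacement at end systole, cm.
        ``x0 > 0``.
    """

    c: float
    k: float
    x0: float

    def __post_init__(self):
        if not (np.isfinite(self.c) and np.isfinite(self.k) and np.isfinite(self.x0)):
            raise InvalidParametersError(f"non-finite parameters {self}")
        if self.k <= 0 or self.x0 <= 0 or self.c < 0:
            raise InvalidParametersError(
                f"require k>0, x0>0, c>=0; got c={self.c}, k={self.k}, x0={self.x0}"
            )

    @property
    def discriminant(self) -> float:
        """Damping index β = c² − 4k, g²/s²; negative for oscillatory recoil."""
        return self.c**2 - 4.0 * self.k

    @property
    def regime(self) -> str:
        """One of ``"underdamped"``, ``"critical"``, ``"overdamped"``."""
        disc = self.discriminant
        if abs(disc) <= _CRITICAL_RTOL * 4.0 * self.k:
            return "critical"
        return "underdamped" if disc < 0 else "overdamped"

    @property
    def omega(self) -> float:
        """Damped angular frequency √(k − c²/4), s⁻¹ (underdamped only)."""
        if self.regime != "underdamped":
            raise InvalidParametersError("omega defined only for underdamped motion")
        return math.sqrt(self.k - 0.25 * self.c**2)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c, self.k, self.x0)


@dataclass(frozen=True)
class DerivedIndices:
    """Physiological indices derived from one fitted E-wave.

    ``vmax`` cm/s peak velocity; ``at`` s acceleration time (onset to peak);
    ``edec`` ms deceleration time (peak to model terminus); ``duration`` s;
    ``vti`` cm velocity–time integral; ``kx0`` mN peak driving force;
    ``cvmax`` mN peak resistive force; ``energy`` mJ stored filling energy
    ½kx0²; ``beta`` g²/s² damping index c²−4k; ``kfei`` % kinematic filling
    efficiency index; ``tau`` ms estimated isovolumic pressure-decay constant
    (NaN when the approximation is not applicable).
    """

    vmax: float
    at: float
    edec: float
    duration: float
    vti: float
    kx0: float
    cvmax: float
    energy: float
    beta: float
    kfei: float
    tau: float

    @property
    def vmax_m_s(self) -> float:
        """Peak velocity in m/s, the unit echocardiography reports."""
        return self.vmax / 100.0


@dataclass(frozen=True)
class Triad:
    """Alternative parameterization: acceleration time, deceleration time and
    peak velocity fully determine a damped-recoil E-wave."""

    at: float  # s, onset -> peak
    dt: float  # s, peak -> terminus
    vmax: float  # cm/s

    def __post_init__(self):
        if self.at <= 0 or self.dt <= 0 or self.vmax <= 0:
            raise InvalidParametersError(
                f"triad components must be positive: {self}"
            )


@dataclass(frozen=True)
class LoadIndependentIndex:
    """Slope M and intercept B of peak driving force (kx0) against peak
    resistive force (cVmax) across beats under varying load."""

    m: float  # dimensionless slope
    b: float  # mN intercept
    n_beats: int
    force_pairs: tuple[tuple[float, float], ...]  # (kx0, cvmax) in mN


def _speed_arrays(params: PDFParameters, t: np.ndarray) -> np.ndarray:
    c, k, x0 = params.c, params.k, params.x0
    regime = params.regime
    env = k * x0 * np.exp(-0.5 * c * t)
    if regime == "underdamped":
        w = params.omega
        v = env * np.sin(w * t) / w
        # the wave ends at its first zero crossing; speed is zero afterwards
        v = np.where(t > math.pi / w, 0.0, v)
    elif regime == "critical":
        v = env * t
    else:
        b = math.sqrt(0.25 * c**2 - k)
        # sinh(bt)/b, written to avoid overflow: e^{-ct/2}·sinh(bt) with b < c/2
        v = 0.5 * k * x0 * (np.exp((b - 0.5 * c) * t) - np.exp((-b - 0.5 * c) * t)) / b
    return np.maximum(v, 0.0)


def model_velocity(params: PDFParameters, t):
    """Transmitral speed |ẋ(t)| of the damped recoil, cm/s.

    Parameters
    ----------
    params : PDFParameters
    t : float or array_like
        Time since flow onset, s.  Must be non-negative.

    Returns
    -------
    float or ndarray
        Non-negative speed; zero at ``t = 0`` and, for oscillatory recoil,
        for all times past the first zero crossing at π/ω.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    v = _speed_arrays(params, t_arr)
    return float(v) if np.isscalar(t) or t_arr.ndim == 0 else v


def peak_characteristics(params: PDFParameters) -> tuple[float, float]:
    """Time of peak velocity and the peak velocity itself.

    Closed forms from dv/dt = 0: underdamped t_peak = atan(2ω/c)/ω (π/(2√k)
    when c = 0); critical t_peak = 2/c; overdamped t_peak = artanh(2β/c)/β.
    """
    c, k = params.c, params.k
    regime = params.regime
    if regime == "underdamped":
        w = params.omega
        t_peak = math.pi / (2.0 * w) if c == 0 else math.atan2(2.0 * w, c) / w
    elif regime == "critical":
        t_peak = 2.0 / c
    else:
        b = math.sqrt(0.25 * c**2 - k)
        t_peak = math.atanh(2.0 * b / c) / b
    return t_peak, float(model_velocity(params, t_peak))


def ewave_duration(params: PDFParameters, decay_fraction: float = 0.01) -> float:
    """Model E-wave duration, s.

    Underdamped recoil returns to zero velocity at π/ω, the wave terminus.
    Critically damped and overdamped recoil never reach zero; by convention
    the wave is considered over once speed has decayed to ``decay_fraction``
    of the peak (default 1 %), which keeps the velocity–time integral and the
    deceleration time finite.
    """
    if params.regime == "underdamped":
        return math.pi / params.omega
    t_peak, vmax = peak_characteristics(params)
    target = decay_fraction * vmax
    hi = 2.0 * t_peak
    while model_velocity(params, hi) > target:
        hi *= 2.0
    return float(
        optimize.brentq(lambda t: model_velocity(params, t) - target, t_peak, hi)
    )


def velocity_time_integral(params: PDFParameters) -> float:
    """Area under the speed curve over the wave duration, cm.

    For oscillatory recoil the closed form is the total excursion of the
    spring, x0·(1 + e^(−cπ/2ω)); otherwise adaptive quadrature over the
    (decay-threshold) duration is used.
    """
    if params.regime == "underdamped":
        c, w = params.c, params.omega
        return params.x0 * (1.0 + math.exp(-0.5 * c * math.pi / w))
    dur = ewave_duration(params)
    val, _ = integrate.quad(lambda t: model_velocity(params, t), 0.0, dur, limit=200)
    return float(val)


def kinematic_filling_efficiency(params: PDFParameters) -> float:
    """KFEI, %: VTI of the wave relative to the VTI of an ideal undamped
    (c = 0) wave with the same k and x0, whose VTI is 2·x0.

    Depends only on (c, k); equals 100 % in the undamped limit and tends to
    50 % as damping removes the elastic rebound.
    """
    return 100.0 * velocity_time_integral(params) / (2.0 * params.x0)


def tau_estimate(params: PDFParameters) -> float:
    """PDF-based approximation of tau, the isovolumic pressure-decay
    constant, in ms.

    When damping dominates inertia the recoil force balance reduces to
    c·ẋ + k·x ≈ 0, an exponential relaxation with time constant c/k; that
    quasi-static constant, expressed in ms, is used as the tau estimate.  It
    increases with impaired relaxation (larger c) and is independent of load.
    Returns NaN when the approximation is not applicable (c = 0: no viscous
    relaxation to time).
    """
    if params.c == 0:
        return float("nan")
    return 1000.0 * params.c / params.k


def derived_indices(params: PDFParameters, decay_fraction: float = 0.01) -> DerivedIndices:
    """All derived physiological indices for one set of constants.

    Forces are converted dyn→mN and energy erg→mJ so the numbers carry the
    units used in clinical reporting.
    """
    t_peak, vmax = peak_characteristics(params)
    dur = ewave_duration(params, decay_fraction)
    vti = velocity_time_integral(params)
    return DerivedIndices(
        vmax=vmax,
        at=t_peak,
        edec=(dur - t_peak) * 1000.0,
        duration=dur,
        vti=vti,
        kx0=params.k * params.x0 * DYN_TO_MN,
        cvmax=params.c * vmax * DYN_TO_MN,
        energy=0.5 * params.k * params.x0**2 * ERG_TO_MJ,
        beta=params.discriminant,
        kfei=100.0 * vti / (2.0 * params.x0),
        tau=tau_estimate(params),
    )


def triad_from_params(params: PDFParameters) -> Triad:
    """Extract the (at, dt, vmax) triad of a damped-recoil wave."""
    t_peak, vmax = peak_characteristics(params)
    dur = ewave_duration(params)
    return Triad(at=t_peak, dt=dur - t_peak, vmax=vmax)


def params_from_triad(triad: Triad) -> PDFParameters:
    """Invert the triad into the model constants (closed form).

    The wave half-period fixes ω = π/(at + dt); the peak condition fixes
    c = 2ω/tan(ω·at); then k = ω² + c²/4 and x0 follows from the peak
    velocity.  Valid for oscillatory (and, in the at = dt limit, undamped)
    waves; ``at > dt`` would require negative damping and is rejected.
    """
    at, dt, vmax = triad.at, triad.dt, triad.vmax
    if at > dt:
        raise NonPhysicalTriadError(
            f"acceleration time {at:.4f}s exceeds deceleration time {dt:.4f}s"
        )
    w = math.pi / (at + dt)
    # at == dt -> ω·at = π/2 -> tan diverges -> c = 0 (symmetric undamped wave)
    tan_wat = math.tan(w * at)
    c = 0.0 if not math.isfinite(tan_wat) or tan_wat <= 0 else 2.0 * w / tan_wat
    if c < 1e-12:
        c = 0.0
    k = w**2 + 0.25 * c**2
    x0 = vmax * w / (k * math.exp(-0.5 * c * at) * math.sin(w * at))
    return PDFParameters(c=c, k=k, x0=x0)


def load_independence(fits: Iterable) -> LoadIndependentIndex:
    """Load-independent index of filling from beats under varying load.

    Ordinary least-squares regression of the peak driving force kx0 (mN,
    dependent) on the peak resistive force cVmax (mN, independent) across
    beats.  The slope M is load independent; the intercept B is in mN.

    Parameters
    ----------
    fits : iterable
        ``DerivedIndices`` (or any objects with ``kx0``/``cvmax`` attributes,
        e.g. fit results exposing ``.indices``), or ``(kx0, cvmax)`` pairs
        in mN.
    """
    pairs = []
    for f in fits:
        if hasattr(f, "indices"):
            f = f.indices
        if hasattr(f, "kx0"):
            pairs.append((float(f.kx0), float(f.cvmax)))
        else:
            kx0, cvmax = f
            pairs.append((float(kx0), float(cvmax)))
    if len(pairs) < 2:
        raise ValueError("load_independence requires at least 2 beats")
    kx0 = np.array([p[0] for p in pairs])
    cvmax = np.array([p[1] for p in pairs])
    if np.ptp(cvmax) == 0:
        raise ValueError("load_independence requires varying peak resistive force")
    res = stats.linregress(cvmax, kx0)
    return LoadIndependentIndex(
        m=float(res.slope), b=float(res.intercept),
        n_beats=len(pairs), force_pairs=tuple(pairs),
    )
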