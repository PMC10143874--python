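"""Two-pool magnetization kinetics for hyperpolarized [1-13C]pyruvate.

The model is a single physical compartment with two chemical pools,
pyruvate (P) and lactate (L).  The magnetization state is the 6-vector

    M = (MPx, MPy, MPz, MLx, MLy, MLz)

Free evolution couples only the longitudinal components through
unidirectional label exchange and T1 relaxation:

    dMPz/dt = -(kPL + R1P) * MPz
    dMLz/dt =  kPL * MPz - R1L * MLz

with R1P = 1/T1_pyruvate and R1L = 1/T1_lactate.  Transverse magnetization
carries no dynamics of its own here: every repetition ends with a spoiler
gradient that destroys it, and T2* effects are deliberately outside the
model, so the free-evolution propagator acts as the identity on the
transverse components.

RF excitation is a rotation about the x axis applied to one pool
(spectrally selective pulse) or to both pools (non-selective hard pulse,
as in CSI).  Inflow of freshly injected, hyperpolarized pyruvate is
described by a gamma-shaped bolus deposited onto MPz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PYR_X", "PYR_Y", "PYR_Z", "LAC_X", "LAC_Y", "LAC_Z",
    "PKParams", "GammaInput",
    "relaxation_exchange_propagator", "rf_rotation", "spoil",
    "propagate_tr", "evolve_with_input", "pyruvate_peak_time",
]

# component indices of the 6-vector state
PYR_X, PYR_Y, PYR_Z, LAC_X, LAC_Y, LAC_Z = range(6)

_POOLS = ("pyruvate", "lactate", "both")


def _check_pool(pool: str) -> None:
    if pool not in _POOLS:
        raise ValueError(f"unknown pool {pool!r}; expected one of {_POOLS}")


@dataclass(frozen=True)
class PKParams:
    """Pharmacokinetic parameters of the two-pool model.

    Parameters
    ----------
    kpl : float
        Apparent pyruvate-to-lactate conversion rate constant (1/s).
    t1_pyr, t1_lac : float
        Longitudinal relaxation times of pyruvate and lactate (s).
    """

    kpl: float = 0.05
    t1_pyr: float = 20.0
    t1_lac: float = 30.0

    def __post_init__(self) -> None:
        if not (self.kpl >= 0):
            raise ValueError(f"kpl must be >= 0, got {self.kpl}")
        if not (self.t1_pyr > 0):
            raise ValueError(f"t1_pyr must be > 0, got {self.t1_pyr}")
        if not (self.t1_lac > 0):
            raise ValueError(f"t1_lac must be > 0, got {self.t1_lac}")

    @property
    def r1p(self) -> float:
        return 1.0 / self.t1_pyr

    @property
    def r1l(self) -> float:
        return 1.0 / self.t1_lac

    def to_dict(self) -> dict:
        return {"kpl": self.kpl, "t1_pyr": self.t1_pyr, "t1_lac": self.t1_lac}

    @classmethod
    def from_dict(cls, d: dict) -> "PKParams":
        return cls(kpl=d["kpl"], t1_pyr=d["t1_pyr"], t1_lac=d["t1_lac"])


def generator_matrix(params: PKParams) -> np.ndarray:
    """6x6 generator R of free evolution (zero on transverse components)."""
    R = np.zeros((6, 6))
    R[PYR_Z, PYR_Z] = -(params.kpl + params.r1p)
    R[LAC_Z, PYR_Z] = params.kpl
    R[LAC_Z, LAC_Z] = -params.r1l
    return R


def relaxation_exchange_propagator(params: PKParams, dt: float) -> np.ndarray:
    """Closed-form ``expm(R * dt)`` for the free-evolution generator.

    Parameters
    ----------
    params : PKParams
    dt : float
        Evolution time in seconds, must be non-negative.

    Returns
    -------
    (6, 6) ndarray acting on magnetization state vectors.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    a = params.kpl + params.r1p   # total pyruvate longitudinal loss rate
    b = params.r1l
    ep = math.exp(-a * dt)
    el = math.exp(-b * dt)
    if abs(a - b) > 1e-12:
        cross = params.kpl * (el - ep) / (a - b)
    else:
        cross = params.kpl * dt * ep
    A = np.eye(6)
    A[PYR_Z, PYR_Z] = ep
    A[LAC_Z, PYR_Z] = cross
    A[LAC_Z, LAC_Z] = el
    return A


def rf_rotation(flip_deg: float, pool: str = "both") -> np.ndarray:
    """Rotation matrix for an RF pulse of the given flip angle.

    The rotation is about the x axis, tipping longitudinal magnetization
    into the transverse plane.  ``pool`` selects which chemical pool the
    pulse excites; the other pool is untouched (spectral selectivity).
    """
    _check_pool(pool)
    if not np.isfinite(flip_deg):
        raise ValueError(f"flip angle must be finite, got {flip_deg}")
    c = math.cos(math.radians(flip_deg))
    s = math.sin(math.radians(flip_deg))
    rx = np.array([[1.0, 0.0, 0.0],
                   [0.0, c, s],
                   [0.0, -s, c]])
    A = np.eye(6)
    if pool in ("pyruvate", "both"):
        A[0:3, 0:3] = rx
    if pool in ("lactate", "both"):
        A[3:6, 3:6] = rx
    return A


def spoil(pool: str = "both") -> np.ndarray:
    """Spoiler matrix: zeroes the transverse components of the selected pool(s)."""
    _check_pool(pool)
    d = np.ones(6)
    if pool in ("pyruvate", "both"):
        d[PYR_X] = d[PYR_Y] = 0.0
    if pool in ("lactate", "both"):
        d[LAC_X] = d[LAC_Y] = 0.0
    return np.diag(d)


def propagate_tr(state: np.ndarray, flip_deg: float, params: PKParams,
                 tr: float, pool: str = "both") -> np.ndarray:
    """One repetition: free evolution over TR, spoiling, then excitation.

    Operators are applied right-to-left: ``rot(flip) @ spoil @ expm(R*TR)``.
    The transverse components of the returned state are the acquirable
    signal immediately after the pulse.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (6,):
        raise ValueError(f"state must be a 6-vector, got shape {state.shape}")
    A = relaxation_exchange_propagator(params, tr)
    return rf_rotation(flip_deg, pool) @ spoil(pool) @ A @ state


# ---------------------------------------------------------------------------
# Bolus input function


def _gamma_unit_fwhm(shape: float) -> float:
    """FWHM of the gamma(shape, scale=1) density (requires shape > 1)."""
    dist = stats.gamma(shape)
    mode = shape - 1.0
    peak = dist.pdf(mode)
    f = lambda x: dist.pdf(x) - 0.5 * peak
    left = optimize.brentq(f, 1e-12, mode)
    hi = mode + 1.0
    while dist.pdf(hi) > 0.5 * peak:
        hi *= 2.0
    right = optimize.brentq(f, mode, hi)
    return right - left


@dataclass(frozen=True)
class GammaInput:
    """Gamma-shaped bolus of hyperpolarized pyruvate.

    The curve is zero before ``arrival_time``, integrates to ``amplitude``
    (arbitrary magnetization units) and has the stated full width at half
    maximum.  ``shape`` controls rise/decay asymmetry; the gamma scale is
    solved so the density's FWHM equals ``fwhm``.
    """

    fwhm: float = 8.0
    arrival_time: float = 0.0
    amplitude: float = 1.0
    shape: float = 4.0
    scale: float = field(init=False)

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.shape <= 1:
            raise ValueError("shape must exceed 1 for a well-defined FWHM")
        object.__setattr__(self, "scale", self.fwhm / _gamma_unit_fwhm(self.shape))

    def pdf(self, t):
        """Normalized bolus rate at time t (integrates to 1)."""
        t = np.asarray(t, dtype=float)
        return stats.gamma.pdf(t - self.arrival_time, self.shape, scale=self.scale)

    def cumulative(self, t):
        """Magnetization delivered up to time t."""
        t = np.asarray(t, dtype=float)
        return self.amplitude * stats.gamma.cdf(
            t - self.arrival_time, self.shape, scale=self.scale)

    def sample(self, times) -> np.ndarray:
        """Per-interval deposited longitudinal pyruvate on a monotone grid.

        Element i is the magnetization arriving in ``(times[i-1], times[i]]``
        (for i = 0: everything up to ``times[0]``), so the samples sum to
        the cumulative delivery at the final grid point.
        """
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be non-decreasing")
        cum = self.cumulative(times)
        out = np.empty_like(cum)
        out[0] = cum[0]
        out[1:] = np.diff(cum)
        return out

    def peak_time(self) -> float:
        """Time of the bolus-rate maximum (gamma mode)."""
        return self.arrival_time + (self.shape - 1.0) * self.scale

    def to_dict(self) -> dict:
        return {
            "input_fwhm": self.fwhm,
            "arrival_time": self.arrival_time,
            "amplitude": self.amplitude,
            "gamma_shape": self.shape,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GammaInput":
        return cls(
            fwhm=d.get("input_fwhm", 8.0),
            arrival_time=d.get("arrival_time", 0.0),
            amplitude=d.get("amplitude", 1.0),
            shape=d.get("gamma_shape", 4.0),
        )


def evolve_with_input(params: PKParams, input_fn: GammaInput, t_end: float,
                      state: np.ndarray | None = None, dt: float = 0.01) -> np.ndarray:
    """Free (RF-off) evolution from t = 0 to ``t_end`` with bolus inflow.

    The bolus is deposited onto MPz at the start of each integration step;
    used to construct the magnetization state at an arbitrary time of the
    dynamic experiment (e.g. the start of a CSI frame).
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    M = np.zeros(6) if state is None else np.array(state, dtype=float)
    if t_end == 0:
        return M
    n = max(1, int(math.ceil(t_end / dt)))
    times = np.linspace(0.0, t_end, n + 1)
    deposits = input_fn.sample(times)
    step = relaxation_exchange_propagator(params, times[1] - times[0])
    M[PYR_Z] += deposits[0]
    for k in range(1, n + 1):
        M = step @ M
        M[PYR_Z] += deposits[k]
    return M


def pyruvate_peak_time(params: PKParams, input_fn: GammaInput,
                       t_max: float = 60.0, dt: float = 0.05) -> float:
    """Time at which longitudinal pyruvate peaks under RF-free bolus dynamics."""
    n = int(round(t_max / dt))
    times = np.linspace(0.0, t_max, n + 1)
    deposits = input_fn.sample(times)
    step_ep = math.exp(-(params.kpl + params.r1p) * dt)
    mz = np.empty(n + 1)
    cur = deposits[0]
    mz[0] = cur
    for k in range(1, n + 1):
        cur = cur * step_ep + deposits[k]
        mz[k] = cur
    return float(times[int(np.argmax(mz))])
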