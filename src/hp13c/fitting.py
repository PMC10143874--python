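"""Inputless one-compartment k_PL fitting.

The fit treats the *measured* pyruvate timecourse as the driving input of
the lactate equation, avoiding any arterial-input model.  With flip
angles alpha_P, alpha_L, timepoints t_n and dt = t_{n+1} - t_n:

    Mhat_Pz(t_n) = P_n / sin(alpha_P)              (pre-pulse estimate)
    Lz(t_{n+1})  = Lz(t_n) * cos(alpha_L) * exp(-dt / T1L)
                   + k_PL * Mhat_Pz(t_n) * cos(alpha_P)
                     * (exp(-dt/T1L) - exp(-a*dt)) / (a - 1/T1L),
      a = k_PL + 1/T1P
    Lhat_{n+1}   = Lz(t_{n+1}) * sin(alpha_L)

i.e. longitudinal lactate survives each interval through RF loss and T1
decay, and gains converted pyruvate through the exact one-interval
solution of the two-pool exchange driven by the interval-start pyruvate
sample (post-RF, hence the cos(alpha_P) factor).  Freshly arrived
pyruvate first shows up in the *next* pyruvate sample, so the
interval-start sample is the correct driver during bolus inflow; with
the interval-exact kernel the fit inverts the discrete acquisition model
without quadrature bias.  The first lactate sample initializes Lz.
k_PL is the single free parameter, estimated by bounded least squares;
the relaxation times are fixed (defaults 30 s lactate, 20 s pyruvate,
matching the simulation parameter set) because they are not separately
identifiable at typical SNR.

The model/results pair follows the statsmodels convention:
``InputlessKplModel(...).fit()`` returns ``KplFitResults`` with the
estimate, an asymptotic standard error, diagnostics, ``predict`` and
``summary``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "InputlessKplModel", "KplFitResults", "fit_kpl",
    "DynamicImageSeries", "noise_normalize", "auc_map", "fit_kpl_map",
]


class InputlessKplModel:
    """Inputless pyruvate->lactate kinetic model for one voxel or ROI.

    Parameters
    ----------
    pyr, lac : array_like
        Measured magnitude timecourses (post-excitation signal).
    times : array_like
        Timepoint times in seconds (monotone increasing).
    pyr_flip, lac_flip : float
        Flip angles in degrees used at acquisition.
    t1_lac, t1_pyr : float
        Fixed relaxation times in seconds.
    bounds : (float, float)
        Box constraint on k_PL in 1/s.
    """

    def __init__(self, pyr, lac, times, pyr_flip, lac_flip,
                 t1_lac: float = 30.0, t1_pyr: float = 20.0,
                 bounds: tuple = (0.0, 1.0)):
        self.pyr = np.asarray(pyr, dtype=float)
        self.lac = np.asarray(lac, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if not (self.pyr.shape == self.lac.shape == self.times.shape):
            raise ValueError("pyr, lac and times must have equal shapes")
        if self.times.size < 3:
            raise ValueError("need at least 3 timepoints to fit k_PL")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.any(self.pyr):
            raise ValueError("all-zero pyruvate timecourse: k_PL unidentifiable")
        sp = math.sin(math.radians(pyr_flip))
        sl = math.sin(math.radians(lac_flip))
        if sp <= 0 or sl <= 0:
            raise ValueError("flip angles must have positive sine")
        self.pyr_flip = float(pyr_flip)
        self.lac_flip = float(lac_flip)
        self.t1_lac = float(t1_lac)
        self.t1_pyr = float(t1_pyr)
        self.bounds = (float(bounds[0]), float(bounds[1]))

        # precompute per-interval quantities
        cp = math.cos(math.radians(pyr_flip))
        self._mhat_pz_cos = self.pyr / sp * cp      # post-RF longitudinal pyruvate
        self._sl = sl
        self._cl = math.cos(math.radians(lac_flip))
        self._dt = np.diff(self.times)
        self._decay = np.exp(-self._dt / self.t1_lac)

    @classmethod
    def from_timecourse(cls, timecourse, protocol, **kwargs) -> "InputlessKplModel":
        """Build from a ``SignalTimecourse`` and its ``AcquisitionProtocol``."""
        return cls(timecourse.pyr, timecourse.lac, timecourse.times,
                   protocol.flips["pyruvate"], protocol.flips["lactate"],
                   **kwargs)

    def predict_lactate(self, kpl: float) -> np.ndarray:
        """Forward lactate signal prediction for a given k_PL."""
        n = self.times.size
        b = 1.0 / self.t1_lac
        a = kpl + 1.0 / self.t1_pyr
        lz = np.empty(n)
        lz[0] = self.lac[0] / self._sl
        m = self._mhat_pz_cos
        for i in range(n - 1):
            dt = self._dt[i]
            el = self._decay[i]
            if abs(a - b) > 1e-12:
                kernel = (el - math.exp(-a * dt)) / (a - b)
            else:
                kernel = dt * el
            lz[i + 1] = lz[i] * self._cl * el + kpl * m[i] * kernel
        return lz * self._sl

    def _residuals(self, kpl_vec) -> np.ndarray:
        return self.predict_lactate(kpl_vec[0]) - self.lac

    def fit(self, start: float = 0.02) -> "KplFitResults":
        """Bounded scalar least squares on k_PL (deterministic)."""
        start = min(max(start, self.bounds[0]), self.bounds[1])
        sol = least_squares(self._residuals, x0=[start], bounds=self.bounds,
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        kpl_hat = float(sol.x[0])
        resid = sol.fun
        # asymptotic standard error from the scalar Jacobian
        jac = np.asarray(sol.jac).ravel()
        jtj = float(jac @ jac)
        dof = max(1, resid.size - 1)
        sigma2 = float(resid @ resid) / dof
        bse = math.sqrt(sigma2 / jtj) if jtj > 0 else math.inf
        eps = 1e-6 * max(1.0, self.bounds[1] - self.bounds[0])
        pinned = (kpl_hat - self.bounds[0] < eps) or (self.bounds[1] - kpl_hat < eps)
        return KplFitResults(
            model=self, kpl_hat=kpl_hat, bse=bse,
            residual_norm=float(np.linalg.norm(resid)),
            converged=bool(sol.success), pinned=pinned,
            n_points_used=int(self.times.size))


@dataclass
class KplFitResults:
    """Result of an inputless k_PL fit."""

    model: InputlessKplModel
    kpl_hat: float
    bse: float
    residual_norm: float
    converged: bool
    pinned: bool
    n_points_used: int

    @property
    def resid(self) -> np.ndarray:
        return self.model.lac - self.predict()

    def predict(self) -> np.ndarray:
        return self.model.predict_lactate(self.kpl_hat)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Inputless k_PL fit",
            "==================",
            f"  n timepoints      : {self.n_points_used}",
            f"  flips (P, L)      : {m.pyr_flip:.1f} deg, {m.lac_flip:.1f} deg",
            f"  T1 lac/pyr (fixed): {m.t1_lac:.1f} s / {m.t1_pyr:.1f} s",
            f"  k_PL estimate     : {self.kpl_hat:.5f} 1/s",
            f"  std. error        : {self.bse:.5f} 1/s",
            f"  residual norm     : {self.residual_norm:.4g}",
            f"  converged         : {self.converged}",
            f"  bound-pinned      : {self.pinned}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.times, m.lac, "s", label="lactate (measured)")
        ax.plot(m.times, self.predict(), "-", label="lactate (fit)")
        ax.plot(m.times, m.pyr, "o", alpha=0.4, label="pyruvate (driver)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("signal (a.u.)")
        ax.legend()
        return ax


def fit_kpl(pyr, lac, flips, times, t1_lac: float = 30.0,
            bounds: tuple = (0.0, 1.0), start: float = 0.02) -> KplFitResults:
    """One-call inputless k_PL fit.

    ``flips`` is a (pyruvate, lactate) pair in degrees.  If lactate is
    identically zero the estimate rests at the lower bound rather than
    erroring.
    """
    model = InputlessKplModel(pyr, lac, times, flips[0], flips[1],
                              t1_lac=t1_lac, bounds=bounds)
    return model.fit(start=start)


# ---------------------------------------------------------------------------
# Image-series level operations


@dataclass
class DynamicImageSeries:
    """4-D dynamic metabolite image stack.

    ``data`` has axes (metabolite, time, y, x) and holds magnitude
    images; ``metabolites`` names the first axis; ``flips`` maps each
    metabolite to its flip angle in degrees; ``noise_mask`` marks a
    spatial region outside the subject used for noise normalization.
    """

    data: np.ndarray
    times: np.ndarray
    metabolites: tuple
    flips: dict
    noise_mask: np.ndarray | None = None
    voxel_mm: float | None = None
    masks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.metabolites = tuple(self.metabolites)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (metabolite, time, y, x)")
        if self.data.shape[0] != len(self.metabolites):
            raise ValueError("metabolite axis length does not match labels")
        if self.data.shape[1] != self.times.size:
            raise ValueError("time axis length does not match times")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")
        if self.noise_mask is not None:
            self.noise_mask = np.asarray(self.noise_mask, dtype=bool)
            if self.noise_mask.shape != self.data.shape[2:]:
                raise ValueError("noise_mask shape does not match image grid")

    def index(self, metabolite: str) -> int:
        return self.metabolites.index(metabolite)

    def voxel_timecourse(self, metabolite: str, iy: int, ix: int) -> np.ndarray:
        return self.data[self.index(metabolite), :, iy, ix]


def noise_normalize(series: DynamicImageSeries) -> tuple[DynamicImageSeries, float]:
    """Scale the series by the mean signal in the noise region.

    The noise level is the mean over time and space of all metabolite
    images within ``noise_mask``; all data are divided by it so the
    normalized noise-region mean is 1.  Returns (normalized series,
    noise level used).
    """
    if series.noise_mask is None or not np.any(series.noise_mask):
        raise ValueError("series has an empty noise mask")
    level = float(series.data[:, :, series.noise_mask].mean())
    if level <= 0:
        raise ValueError("noise-region mean is zero; cannot normalize")
    out = DynamicImageSeries(
        data=series.data / level, times=series.times,
        metabolites=series.metabolites, flips=dict(series.flips),
        noise_mask=series.noise_mask, voxel_mm=series.voxel_mm,
        masks=dict(series.masks))
    return out, level


def auc_map(series: DynamicImageSeries) -> dict:
    """Per-metabolite area-under-the-curve images (sum over time)."""
    return {m: series.data[i].sum(axis=0)
            for i, m in enumerate(series.metabolites)}


def fit_kpl_map(series: DynamicImageSeries, roi_mask: np.ndarray,
                t1_lac: float = 30.0, snr_floor: float = 3.0,
                noise_level: float = 1.0) -> tuple[np.ndarray, KplFitResults]:
    """Voxelwise and ROI-average inputless k_PL fits.

    One fit is run on the ROI-mean pyruvate/lactate timecourses and one
    per ROI voxel.  Voxels whose peak lactate signal falls below
    ``snr_floor * noise_level`` are left NaN in the map (they would pin at
    the optimizer bounds).  Returns ``(kpl_map, roi_result)``.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != series.data.shape[2:]:
        raise ValueError("roi_mask shape does not match image grid")
    if not np.any(roi_mask):
        raise ValueError("empty ROI")
    ip = series.index("pyruvate")
    il = series.index("lactate")
    flips = (series.flips["pyruvate"], series.flips["lactate"])

    roi_pyr = series.data[ip][:, roi_mask].mean(axis=1)
    roi_lac = series.data[il][:, roi_mask].mean(axis=1)
    roi_result = fit_kpl(roi_pyr, roi_lac, flips, series.times, t1_lac=t1_lac)

    kpl_map = np.full(roi_mask.shape, np.nan)
    for iy, ix in zip(*np.nonzero(roi_mask)):
        lac_tc = series.data[il, :, iy, ix]
        if lac_tc.max() < snr_floor * noise_level:
            continue
        pyr_tc = series.data[ip, :, iy, ix]
        if not np.any(pyr_tc):
            continue
        kpl_map[iy, ix] = fit_kpl(pyr_tc, lac_tc, flips, series.times,
                                  t1_lac=t1_lac).kpl_hat
    return kpl_map, roi_result
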