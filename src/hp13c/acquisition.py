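"""Dynamic acquisition simulation for metabolite-specific EPI and CSI.

EPI: each metabolite is excited by a spectrally selective pulse and all of
k-space is read in a single shot, so the per-frame k-space weighting is
flat.  The dynamic timecourse model per timepoint is

    deposit bolus -> excite/read pyruvate -> evolve TR_P
                  -> excite/read lactate  -> evolve (TempRes - TR_P)

with the post-excitation transverse magnitude as the acquired signal.

CSI: a non-selective pulse excites both pools once per phase encode; the
hyperpolarized magnetization decays (and lactate builds) across the
encodes, apodizing k-space.  ``simulate_csi_frame_weights`` records the
per-encode transverse amplitude of each pool on the k-space grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .kinetics import (
    PYR_X, PYR_Y, PYR_Z, LAC_X, LAC_Y, LAC_Z,
    GammaInput, PKParams,
    relaxation_exchange_propagator, rf_rotation, spoil,
)

__all__ = [
    "AcquisitionProtocol", "SignalTimecourse", "KSpaceWeights",
    "simulate_epi_dynamics", "order_phase_encodes",
    "simulate_csi_frame_weights", "epi_frame_weights",
]

_ENCODINGS = ("epi_singleshot", "csi")
_ORDERINGS = ("centric", "linear")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition protocol for a dynamic metabolite-specific experiment.

    Parameters
    ----------
    encoding : {"epi_singleshot", "csi"}
    metabolite_order : tuple of str
        Excitation order within a timepoint (e.g. ("pyruvate", "lactate")).
    flips : dict
        Flip angle in degrees per metabolite.
    intra_tr : float
        Spacing between consecutive metabolite excitations within a
        timepoint (the pyruvate-to-lactate delay TR_P), seconds.
    temporal_resolution : float
        Spacing between dynamic timepoints, seconds.
    n_timepoints : int
    matrix : (ny, nx)
    fov : (mm, mm)
    ordering : {"centric", "linear"}
        Phase-encode ordering (CSI only).
    csi_tr : float or None
        Per-phase-encode repetition time (CSI); defaults to
        temporal_resolution / (nx * ny).
    """

    encoding: str = "epi_singleshot"
    metabolite_order: tuple = ("pyruvate", "lactate")
    flips: dict = field(default_factory=lambda: {"pyruvate": 10.0, "lactate": 30.0})
    intra_tr: float = 0.15
    temporal_resolution: float = 3.0
    n_timepoints: int = 18
    matrix: tuple = (16, 16)
    fov: tuple = (32.0, 32.0)
    ordering: str = "centric"
    csi_tr: float | None = None
    t1_urea: float = 20.0

    def __post_init__(self) -> None:
        if self.encoding not in _ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.ordering not in _ORDERINGS:
            raise ValueError(f"unknown ordering {self.ordering!r}")
        object.__setattr__(self, "metabolite_order", tuple(self.metabolite_order))
        object.__setattr__(self, "matrix", tuple(int(v) for v in self.matrix))
        object.__setattr__(self, "fov", tuple(float(v) for v in self.fov))
        for m in self.metabolite_order:
            if m not in self.flips:
                raise ValueError(f"no flip angle given for metabolite {m!r}")
        if any(n < 2 for n in self.matrix):
            raise ValueError(f"matrix dims must be >= 2, got {self.matrix}")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        n_excite = len(self.metabolite_order)
        if self.temporal_resolution < (n_excite - 1) * self.intra_tr:
            raise ValueError(
                "temporal_resolution shorter than the intra-timepoint "
                f"excitation train ({n_excite - 1} x {self.intra_tr} s)")
        if self.encoding == "csi":
            tr = self.effective_csi_tr
            if tr <= 0:
                raise ValueError(f"csi_tr must be > 0, got {tr}")
            if tr * self.matrix[0] * self.matrix[1] > self.temporal_resolution + 1e-9:
                raise ValueError("CSI frame (csi_tr * nx * ny) exceeds the "
                                 "temporal resolution")

    @property
    def voxel_mm(self) -> tuple:
        return (self.fov[0] / self.matrix[0], self.fov[1] / self.matrix[1])

    @property
    def effective_csi_tr(self) -> float:
        if self.csi_tr is not None:
            return self.csi_tr
        return self.temporal_resolution / (self.matrix[0] * self.matrix[1])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.temporal_resolution

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metabolite_order"] = list(self.metabolite_order)
        d["matrix"] = list(self.matrix)
        d["fov"] = list(self.fov)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown protocol keys: {sorted(bad)}")
        return cls(**d)


@dataclass
class SignalTimecourse:
    """Per-timepoint post-excitation signal magnitudes."""

    times: np.ndarray
    pyr: np.ndarray
    lac: np.ndarray
    urea: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pyr = np.asarray(self.pyr, dtype=float)
        self.lac = np.asarray(self.lac, dtype=float)
        if not (len(self.times) == len(self.pyr) == len(self.lac)):
            raise ValueError("times, pyr and lac must have equal length")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.pyr, "o-", label="pyruvate")
        ax.plot(self.times, self.lac, "s-", label="lactate")
        if self.urea is not None:
            ax.plot(self.times, self.urea, "^-", label="urea")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("signal (a.u.)")
        ax.legend()
        return ax


@dataclass
class KSpaceWeights:
    """Relative transverse signal amplitude at each k-space location."""

    metabolite: str
    weights: np.ndarray
    voxel_mm: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-D (ky, kx)")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")


def simulate_epi_dynamics(protocol: AcquisitionProtocol, params: PKParams,
                          input_fn: GammaInput) -> SignalTimecourse:
    """Dynamic pyruvate/lactate (and optional urea) EPI signal timecourses.

    Within each timepoint the bolus increment is deposited on MPz, pyruvate
    is excited (selective pulse, spoiling of its stale transverse first) and
    read, the system evolves for ``intra_tr``, lactate is excited and read,
    and the system evolves through the remaining delay to the next
    timepoint.  Returned signals are post-excitation transverse magnitudes.
    """
    if protocol.encoding != "epi_singleshot":
        raise ValueError("simulate_epi_dynamics requires encoding='epi_singleshot'")
    alpha_p = protocol.flips["pyruvate"]
    alpha_l = protocol.flips["lactate"]
    n = protocol.n_timepoints
    times = protocol.times
    deposits = input_fn.sample(times)

    excite_p = rf_rotation(alpha_p, "pyruvate") @ spoil("pyruvate")
    excite_l = rf_rotation(alpha_l, "lactate") @ spoil("lactate")
    evolve_pl = relaxation_exchange_propagator(params, protocol.intra_tr)
    evolve_rest = relaxation_exchange_propagator(
        params, protocol.temporal_resolution - protocol.intra_tr)

    M = np.zeros(6)
    pyr = np.empty(n)
    lac = np.empty(n)
    for t in range(n):
        M[PYR_Z] += deposits[t]
        M = excite_p @ M
        pyr[t] = math.hypot(M[PYR_X], M[PYR_Y])
        M = evolve_pl @ M
        M = excite_l @ M
        lac[t] = math.hypot(M[LAC_X], M[LAC_Y])
        M = evolve_rest @ M

    urea = None
    if "urea" in protocol.metabolite_order:
        urea = _simulate_urea(protocol, input_fn)
    return SignalTimecourse(times=times, pyr=pyr, lac=lac, urea=urea)


def _simulate_urea(protocol: AcquisitionProtocol, input_fn: GammaInput) -> np.ndarray:
    """Independent non-exchanging urea pool with its own T1 and flip angle."""
    alpha = math.radians(protocol.flips["urea"])
    decay = math.exp(-protocol.temporal_resolution / protocol.t1_urea)
    deposits = input_fn.sample(protocol.times)
    mz = 0.0
    out = np.empty(protocol.n_timepoints)
    for t in range(protocol.n_timepoints):
        mz += deposits[t]
        out[t] = mz * math.sin(alpha)
        mz *= math.cos(alpha) * decay
    return out


def order_phase_encodes(matrix: tuple, ordering: str = "centric") -> list:
    """Acquisition order of phase-encode indices for a (ny, nx) matrix.

    ``centric`` sorts indices by Euclidean distance from the k-space
    center (index (ny//2, nx//2), standard DFT convention), ties broken by
    angle from the +kx axis counter-clockwise; ``linear`` is row-major.
    Returns a list of (ky, kx) tuples covering every encode exactly once.
    """
    ny, nx = int(matrix[0]), int(matrix[1])
    if ny < 1 or nx < 1:
        raise ValueError(f"matrix dims must be >= 1, got {matrix}")
    if ordering == "linear":
        return [(ky, kx) for ky in range(ny) for kx in range(nx)]
    if ordering != "centric":
        raise ValueError(f"unknown ordering {ordering!r}")
    cy, cx = ny // 2, nx // 2

    def key(idx):
        dy, dx = idx[0] - cy, idx[1] - cx
        dist = math.hypot(dy, dx)
        ang = math.atan2(dy, dx) % (2.0 * math.pi)
        return (dist, ang)

    return sorted(((ky, kx) for ky in range(ny) for kx in range(nx)), key=key)


def simulate_csi_frame_weights(protocol: AcquisitionProtocol, params: PKParams,
                               start_state: np.ndarray,
                               input_fn: GammaInput | None = None,
                               frame_start_time: float = 0.0,
                               ) -> tuple[KSpaceWeights, KSpaceWeights]:
    """Per-metabolite k-space weights across one CSI frame.

    Walks the ordered phase-encode list; at each encode a non-selective
    pulse excites both pools, the post-excitation transverse magnitude of
    each pool is recorded at that k index, the transverse magnetization is
    spoiled, and the system evolves for one per-encode TR including any
    bolus inflow.  ``start_state`` is the magnetization at the start of the
    frame (``frame_start_time`` on the bolus clock).
    """
    if protocol.encoding != "csi":
        raise ValueError("simulate_csi_frame_weights requires encoding='csi'")
    tr = protocol.effective_csi_tr
    if tr <= 0:
        raise ValueError(f"csi_tr must be > 0, got {tr}")
    ny, nx = protocol.matrix
    flip = protocol.flips["pyruvate"]  # non-selective pulse: one angle
    excite = rf_rotation(flip, "both")
    kill = spoil("both")
    evolve = relaxation_exchange_propagator(params, tr)
    order = order_phase_encodes(protocol.matrix, protocol.ordering)

    n_enc = ny * nx
    if input_fn is not None:
        enc_times = frame_start_time + tr * np.arange(n_enc)
        deposits = input_fn.sample(enc_times)
        deposits[0] = 0.0  # start_state already includes delivery up to frame start
    else:
        deposits = np.zeros(n_enc)

    M = np.array(start_state, dtype=float)
    wp = np.zeros((ny, nx))
    wl = np.zeros((ny, nx))
    for j, (ky, kx) in enumerate(order):
        M[PYR_Z] += deposits[j]
        M = excite @ M
        wp[ky, kx] = math.hypot(M[PYR_X], M[PYR_Y])
        wl[ky, kx] = math.hypot(M[LAC_X], M[LAC_Y])
        M = evolve @ (kill @ M)

    vox = protocol.voxel_mm[0]
    return (KSpaceWeights("pyruvate", wp, vox), KSpaceWeights("lactate", wl, vox))


def epi_frame_weights(protocol: AcquisitionProtocol,
                      metabolite: str = "pyruvate") -> KSpaceWeights:
    """Flat k-space weights of a single-shot EPI frame.

    All of k-space is acquired in one shot per metabolite; within-readout
    T2* decay is outside the model, so the weighting is uniform.
    """
    if protocol.encoding != "epi_singleshot":
        raise ValueError("epi_frame_weights requires encoding='epi_singleshot'")
    return KSpaceWeights(metabolite, np.ones(protocol.matrix), protocol.voxel_mm[0])
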