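# Methods

## Two-pool kinetic model

The magnetization of pyruvate and lactate in a single physical
compartment is tracked as the 6-vector
M = (M_Px, M_Py, M_Pz, M_Lx, M_Ly, M_Lz). Free evolution couples only
the longitudinal components:

    dM_Pz/dt = −(k_PL + R1P)·M_Pz
    dM_Lz/dt =  k_PL·M_Pz − R1L·M_Lz,   R1P = 1/T1P, R1L = 1/T1L

Exchange is unidirectional (no k_LP back-conversion); alanine and
bicarbonate pools and vascular/extravascular compartmentalization are out
of scope. The propagator over an interval dt is the closed-form matrix
exponential of this 2×2 longitudinal system embedded in the 6×6 identity;
the off-diagonal (conversion) term is

    k_PL · (e^{−R1L·dt} − e^{−a·dt}) / (a − R1L),   a = k_PL + R1P,

with the limit k_PL·dt·e^{−a·dt} when a → R1L. Transverse components are
untouched by free evolution: a spoiler follows every excitation, so
transverse magnetization never survives an interval, and T₂/T₂* effects
are deliberately outside the model (the EPI readout is ~100 ms, short
against metabolite T₂). RF excitation is a rotation about the x axis
applied to one pool (spectrally selective pulse) or both (non-selective
CSI pulse); the rotation axis is arbitrary because only post-excitation
transverse *magnitudes* are ever used.

Default kinetic parameters: k_PL = 0.05 s⁻¹, T1P = 20 s, T1L = 30 s —
values representative of in-vivo tumor fitting results.

## Bolus input

Inflow of injected pyruvate is a gamma-density bolus deposited onto
M_Pz. The full width at half maximum is the constrained property
(default 8 s); the gamma shape parameter k (default 4) sets rise/decay
asymmetry and is exposed as a configuration knob, with the scale solved
numerically so the density's FWHM matches the requested value. The bolus
is deposited discretely: at each timepoint (EPI) or each phase-encode TR
(CSI) the mass that arrived since the previous deposit is added to M_Pz
in one lump before excitation. By default the bolus starts at the
beginning of the acquisition window (arrival_time = 0), so an
18-timepoint, 3 s run covers the inflow, the peak (RF-free M_Pz peak at
~11 s) and most of the washout.

## Dynamic EPI model

Per timepoint: deposit the bolus increment; excite pyruvate (selective
pulse, preceded by a pyruvate-pool spoiler) and read |M_Pxy|; evolve for
the intra-timepoint delay TR_P; excite and read lactate; evolve through
the remainder of the temporal resolution. TR_P defaults to 0.15 s
(a ~25 ms spectral-spatial pulse plus a ~100 ms EPI readout plus
overhead); the simulated optima are insensitive to TR_P at this scale.
Relative SNR of a metabolite is the sum of its magnitude signal over the
dynamic run — a comparator across protocols, not an absolute SNR.

## CSI model and PSF analysis

CSI acquires one k-space sample per excitation with a hard
(non-selective) pulse, so both pools are excited every per-encode TR
(default: temporal resolution / number of encodes = 4.25/64 ≈ 66.4 ms
for the 8×8 protocol). Centric ordering sorts encodes by Euclidean
distance from the k-space center (DFT convention: index n//2), ties
broken by angle from the +kx axis counter-clockwise — a deterministic
documented choice; measured magnitude PSFs do not depend on it in any
way we assert. Signal decay (RF depletion, T₁, conversion) and lactate
build-up across the encodes apodize k-space.

PSF: the weight map is embedded in a zero-filled grid (default factor
16), inverse DFT'd, magnitude-normalized. Metrics on the central row:
FWHM from the half-maximum crossings of the main lobe and width-at-10%
from the *outermost* 10% crossings (sidelobes included — this is the
reading consistent with a flat 16×16 weighting giving ≈10.8 mm rather
than the ~3.2 mm of the main lobe alone). Crossings are linearly
interpolated between grid samples; with zero-fill 16 both metrics are
stable to <0.1% under grid doubling, and the flat-weighting case agrees
with the analytic Dirichlet (periodic-sinc) kernel to <0.1%. A profile
that never falls below a threshold (e.g. heavily apodized weights whose
far sidelobes stay above 10%) raises an error rather than reporting a
fake width; all-zero weight maps are rejected.

**CSI frame start.** The PSF of a CSI frame depends on where in the
bolus the frame opens — it sets whether pyruvate is decaying and how
fast lactate is still growing across the encodes. The package's default
opens the 4.25 s frame at 1.43× the RF-free pyruvate-peak time (≈15.9 s
for the default bolus), i.e. shortly after the pyruvate peak, with the
start state obtained by integrating the RF-free bolus-driven model to
that time. This is the setting at which the four PSF metrics (pyruvate
and lactate FWHM and width-10%) best match their expected relative
pattern — pyruvate monotonically decaying (center-weighted k-space,
broadened main lobe), lactate rising then falling (edge-shifted
weighting: slightly narrower FWHM, much wider 10% width). The start
time is an exposed parameter (`frame_start`, seconds or "peak" or
"default").

## Protocol optimization

The SNR landscape over (pyruvate flip × lactate flip × temporal
resolution) is filled by vectorized dynamic EPI runs (default axes
1°–90° at 1°, {2, 3, 4, 5} s, 18 timepoints — 32 400 cells, ~1 s).
Pyruvate SNR is exactly independent of the lactate flip (the lactate
pulse is selective); lactate SNR decreases monotonically in pyruvate
flip (RF consumes the substrate) and peaks at an intermediate lactate
flip and a 3 s temporal resolution, reflecting the conversion-time/decay
trade-off.

k_PL fitting precision is estimated by Monte Carlo: simulate the
noiseless curves once, add i.i.d. zero-mean Gaussian noise to the
magnitude timecourses per iteration, refit, and report the standard
deviation of the estimates (default 500 iterations, ~1 s per cell;
estimates pinned at the optimizer bounds are counted and excluded, with
a warning above a 5% pinned fraction). The default noise sd (0.002 in
signal units) puts the peak pyruvate SNR near 50 for the default
unit-amplitude bolus and 10° pyruvate flip — a typical preclinical
level; it is a configuration parameter, not a fitted quantity.
`recommend_protocol` maximizes lactate SNR subject to a minimum
pyruvate-SNR fraction and, when available, a maximum k_PL sd. Computing
the kpl_sd surface on the full 1° grid is combinatorially expensive;
`kpl_sd_grid` accepts arbitrary (typically coarse) axes instead.

## Inputless k_PL fit

The fit avoids an arterial-input model by letting the *measured*
pyruvate drive the lactate equation. Longitudinal pyruvate before the
pulse at t_n is estimated as P_n/sin(α_P); after the pulse it carries the
cos(α_P) factor. Lactate longitudinal magnetization is propagated
between timepoints as

    Lz(t_{n+1}) = Lz(t_n)·cos(α_L)·e^{−dt/T1L}
                  + k_PL·(P_n/sin α_P)·cos α_P·(e^{−dt/T1L} − e^{−a·dt})/(a − 1/T1L)

with a = k_PL + 1/T1P, the first lactate sample initializing Lz, and the
predicted signal Lz·sin(α_L) compared with the measurement. The
conversion term is the interval-exact solution of the two-pool system
driven by the interval-*start* pyruvate sample. This discretization
choice matters: bolus mass is deposited at timepoint starts, so the
pyruvate sample at t_{n+1} contains fresh magnetization that did not
drive conversion during [t_n, t_{n+1}]; a trapezoid over both endpoint
samples mistakes that fresh signal for conversion substrate and biases
k_PL low by ~14% during inflow, whereas the interval-start/exact-kernel
form inverts the acquisition model with negligible residual bias
(<0.1% noiseless, across k_PL 0.01–0.1 and flip schedules).

T1L (30 s) and T1P (20 s) are fixed at the simulation values — they are
not separately identifiable from two magnitude timecourses at realistic
SNR — and both are exposed parameters. The single free parameter k_PL is
estimated by bounded least squares on [0, 1] s⁻¹ from a deterministic
start of 0.02 s⁻¹ (no stochastic restarts); an estimate within 10⁻⁶ of a
bound is flagged as pinned. The reported standard error is the usual
asymptotic least-squares expression from the scalar Jacobian. Voxelwise
maps skip voxels whose peak lactate is below 3× the noise level
(default; such voxels pin at the bounds and carry no information), and
image series are normalized by the mean over time and space of a
noise-region mask before fitting.

## Digital phantom

The phantom emulates the spatial situation that makes encoding choice
matter in small animals: a strongly perfused vessel one voxel away from
a tumor. On a 32×32 grid at 1 mm (32 mm FOV): a 4 mm vessel strip
(perfusion amplitude 12, k_PL 0.02 s⁻¹), a 4 mm-radius tumor disc
centered at (16, 16) mm (perfusion 1, k_PL 0.05 s⁻¹ — the simulation
value) and background tissue (perfusion 0.25, k_PL 0.01 s⁻¹). Geometry
and contrast are package constants chosen so the bleed phenomenon is
robust across noise seeds; they are synthetic stand-ins, not measured
mouse anatomy, and are labelled as such.

Forward imaging: per-region dynamics from the kinetic core (signals are
linear in the perfusion-scaled bolus), assembled into k-space on the
protocol matrix. EPI frames sample the instantaneous object's DFT (flat
single-shot weighting); CSI frames are assembled encode by encode from
the *evolving* object — each phase encode samples the DFT of the image
as it is at that encode's acquisition time, which is precisely the
mechanism that apodizes k-space differently for pyruvate and lactate.
Reconstruction uses a spin-count convention (a voxel integrates the
magnetization it contains), so coarser voxels have higher per-voxel
signal while the added complex Gaussian noise (sd 5×10⁻⁴ per frame,
magnitude taken → Rician) is resolution-independent — reproducing the
higher AUC observed at 4 mm versus 2 mm. All randomness flows through a
single seeded generator; identical (phantom, protocol, seed) triples
give bit-identical series.

The bleed comparison images the same phantom with the 2 mm × 16×16
dynamic EPI protocol and the 4 mm × 8×8 centric CSI protocol (the
resolutions actually used by the two sequence families). The lactate-AUC
profile along the row through the tumor center shows two distinct peaks
(vessel, tumor) under EPI; under CSI the vessel signal bleeds across the
one-voxel gap and the tumor fails a peak-prominence test (threshold:
10% of the profile maximum, `scipy.signal.find_peaks`), leaving a single
peak. This is stable across at least 10 consecutive seeds at the default
noise level.

What the phantom does *not* emulate: anatomical realism, motion,
coil-sensitivity or B₀/B₁ inhomogeneity, Nyquist ghosting, T₂* blur,
partial-volume kinetics (each phantom cell has exactly one region's
parameters). Tests passing on the phantom therefore validate the
encoding/kinetics machinery, not in-vivo image quality.

## Problem sizes and determinism

The test suite and the results script run at the sizes stated above —
18-timepoint dynamics, 8×8/16×16 matrices, zero-fill 16, 500 Monte Carlo
iterations, 32 400-cell SNR grids — all chosen as the natural scales of
the protocols being modelled; the full suite completes in well under a
minute. Every stochastic component (Monte Carlo noise, phantom noise)
takes an explicit integer seed and is bit-reproducible.

## Known limitations

* Unidirectional exchange only; at high lactate pools the neglected
  back-conversion folds into the *apparent* k_PL.
* The inputless fit inherits the acquisition model's assumptions
  (magnitude signals, ideal flips, lump-sum inflow); B₁ errors map
  directly into k_PL bias, as in any flip-angle-corrected fit.
* The CSI PSF depends on the frame-start parameter; reported metrics are
  meaningful only together with that setting.
* Relative SNR ignores noise correlations and reconstruction filters; it
  ranks protocols, it does not predict absolute image SNR.
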