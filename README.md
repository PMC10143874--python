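# hp13c

Simulation, protocol design and pharmacokinetic fitting for preclinical
**hyperpolarized [1-¹³C]pyruvate MRI**.

Hyperpolarized pyruvate imaging watches injected ¹³C-labelled pyruvate
being converted to lactate in vivo — an upregulated conversion is a
metabolic hallmark of many tumors. The magnetization is non-renewable:
every RF excitation and every second of T₁ decay spends signal that never
comes back, so sequence design (flip angles, temporal resolution, k-space
encoding) directly trades off pyruvate SNR, lactate SNR and the precision
of the fitted conversion rate. This package provides the simulation and
analysis machinery for making those trade-offs quantitatively, aimed at
researchers running (or planning) metabolite-specific EPI or CSI
acquisitions on preclinical scanners.

## The model

A single physical compartment with two chemical pools. The magnetization
state is M = (M_Px, M_Py, M_Pz, M_Lx, M_Ly, M_Lz); one repetition is

```
M_n = rot(α) · spoil · expm(R·TR) · M_{n−1}
```

where the free-evolution generator R acts on the longitudinal components
as

```
dM_Pz/dt = −(k_PL + 1/T1P) · M_Pz
dM_Lz/dt =  k_PL · M_Pz − (1/T1L) · M_Lz
```

with defaults k_PL = 0.05 s⁻¹, T1P = 20 s, T1L = 30 s, and a
gamma-shaped bolus (FWHM 8 s) deposited onto M_Pz. On top of this core
the package builds:

* **Dynamic metabolite-specific EPI** — spectrally selective excitation
  per metabolite, whole k-space per shot, signals read post-excitation
  (`simulate_epi_dynamics`).
* **CSI k-space weighting** — one non-selective excitation per phase
  encode (centric or linear order); the decaying/converting magnetization
  apodizes k-space (`simulate_csi_frame_weights`).
* **PSF analysis** — zero-filled inverse DFT of a weight map, FWHM and
  width-at-10%-of-max of the central profile (`weights_to_psf`,
  `profile_metrics`).
* **Protocol optimization** — relative SNR (summed magnitude signal over
  the dynamic run) across flip-angle pairs and temporal resolutions, and
  Monte Carlo precision of the k_PL fit (`snr_grid`, `montecarlo_kpl_sd`,
  `recommend_protocol`).
* **Inputless k_PL fitting** — the measured pyruvate timecourse drives
  the lactate equation; k_PL is the single free parameter, fitted by
  bounded least squares, voxelwise or ROI-averaged
  (`InputlessKplModel`, `fit_kpl_map`).
* **Digital phantom** — a vessel-strip/tumor-disc phantom imaged through
  the full EPI and CSI forward models with Rician noise, reproducing the
  vascular signal-bleed phenomenon (`make_default_phantom`,
  `forward_image`, `bleed_profile`).

## Worked example

```python
from hp13c import (AcquisitionProtocol, GammaInput, InputlessKplModel,
                   PKParams, relative_snr, simulate_epi_dynamics)

params = PKParams(kpl=0.05, t1_pyr=20.0, t1_lac=30.0)
bolus = GammaInput(fwhm=8.0, amplitude=1.0)
protocol = AcquisitionProtocol(flips={"pyruvate": 10.0, "lactate": 30.0},
                               temporal_resolution=3.0, n_timepoints=18)

tc = simulate_epi_dynamics(protocol, params, bolus)
pyr_snr, lac_snr = relative_snr(tc)
print(f"relative SNR  pyruvate: {pyr_snr:.3f}  lactate: {lac_snr:.3f}")

res = InputlessKplModel.from_timecourse(tc, protocol).fit()
print(res.summary())
```

prints

```
relative SNR  pyruvate: 0.636  lactate: 0.934
Inputless k_PL fit
==================
  n timepoints      : 18
  flips (P, L)      : 10.0 deg, 30.0 deg
  T1 lac/pyr (fixed): 30.0 s / 20.0 s
  k_PL estimate     : 0.04998 1/s
  std. error        : 0.00016 1/s
  residual norm     : 0.003136
  converged         : True
  bound-pinned      : False
```

The relative SNRs are the summed magnitude signals over the 18-timepoint
run (arbitrary units, proportional to the bolus amplitude); the fit
recovers the simulated conversion rate of 0.05 s⁻¹ from its own dynamic
curves to within 0.05%, and the standard error is the asymptotic
least-squares uncertainty at this noise level (here: discretization
residuals only).

A command-line surface wraps the same machinery:

```bash
hp13c dynamics --out dynamics.csv           # Eq-style EPI timecourses
hp13c psf --protocol csi.json --out-dir out # PSF profiles + metrics
hp13c optimize --out grid.csv               # SNR landscape (long CSV)
hp13c simulate --out-dir sim --seed 4       # phantom -> dynamic NPZ series
hp13c fit --series sim/series.npz --roi tumor --out-dir fit
```

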