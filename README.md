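# ringpol

Mueller-matrix polarimetry of ring-shaped engineered tissue constructs —
a tested, reusable implementation of the complete analysis chain for
transmission polarimetric imaging of collagenous tissue phantoms:

- a **digital twin of the polarimeter** (polarization state generator /
  analyzer with 6 input states × 8 analyzer configurations = 48 intensity
  frames per measurement, camera noise and 8-bit quantization);
- **eigenvalue calibration** (ECM) recovering the instrument matrices
  `W` (4×6) and `A` (8×4), with their systematic imperfections, from
  acquisitions of air, a linear polarizer at 0/45/90° and a quarter-wave
  plate at 0/45°;
- pixel-wise **Mueller matrix reconstruction** from `B = A M W` via
  pseudo-inverses, and conversion to scalar parameter maps through the
  **Lu–Chipman polar decomposition** (`M = M_Δ M_R M_D`: diattenuation D,
  total/linear/circular retardance R, δ, ψ, total/linear/circular
  depolarization Δ, Δ_L, Δ_C, fast-axis orientation) and the rotation-
  invariant **Mueller matrix transformation** (b, t, degree of anisotropy A);
- **ROI statistics**: MAD-based tissue masking (exclude pixels beyond 3
  scaled median absolute deviations of depolarization), masked means and
  maxima, radial line profiles across the ring with heterogeneity metrics,
  Spearman correlations, Kruskal–Wallis across time points with unadjusted
  pairwise Wilcoxon rank-sum post hoc tests;
- **SHG 3D fiber-orientation analysis**: per-subvolume Fourier-domain axis
  estimation and dispersion statistics including the spherical variance
  `SV = 1 − |Σ vᵢ|/n` of antipodally identified axes, normalized by 0.4;
- a **synthetic-data module** generating ring phantoms (annulus with
  circumferential fast axis, radial retardance profile peaking near the
  inner edge, weak circular depolarization, optional defect spots), a
  two-arm time-course cohort, calibration reference acquisitions and 3D
  fiber volumes — all with machine-readable ground truth.

It is aimed at researchers developing or validating polarimetric imaging
pipelines who need an end-to-end, ground-truthed test bed rather than
bench data.

## Worked example

A homogeneous sample with linear retardance δ = 11.02° (fast axis 30°)
and circular depolarization Δ_C = 0.03544, measured noise-free and
recovered through the full pipeline:

```python
import numpy as np
import ringpol as rp

M = rp.make_diagonal_depolarizer(1, 1, 1 - 0.03544) @ rp.make_linear_retarder(11.02, 30)
inst = rp.ideal_instrument()                 # W (4x6), A (8x4)
stack = rp.forward_acquire(M, inst)          # 48 intensity frames
img = rp.reconstruct_mueller(stack, inst)    # per-pixel M via pseudo-inverses
res = rp.mmpd_decompose(img)                 # Lu-Chipman parameter maps
print(f"delta = {float(res.delta_deg):.4f} deg,  DeltaC = {float(res.DeltaC):.5f}")
print(f"psi   = {abs(float(res.psi_deg)):.1e} deg, DeltaL = {abs(float(res.DeltaL)):.1e}")
```

prints

```
delta = 11.0200 deg,  DeltaC = 0.03544
psi   = 2.4e-15 deg, DeltaL = 8.9e-16
```

i.e. the construction parameters come back exactly, and their
counterparts (circular retardance, linear depolarization) stay at the
numerical floor — the counterpart independence that makes δ and Δ_C
usable as independent dials of a tissue phantom.

With an imperfect instrument, calibrate first:

```python
errs = rp.ArmErrors(polarizer_offset_deg=2.0, qwp_retardance_offset_deg=4.0)
real = rp.build_instrument(rp.ideal_schedule(), psg_errors=errs)
cal = rp.calibrate(rp.make_reference_acquisitions(real))   # ECM
img = rp.reconstruct_mueller(rp.forward_acquire(M, real), cal.instrument)
```

The command-line pipeline (`ringpol simulate / calibrate / analyze /
cohort / shg`) wraps the same functions around TIFF/HDF5/CSV files; every
run writes a manifest with config hash and seeds.

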