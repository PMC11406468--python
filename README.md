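# muellermap

Multispectral Mueller-matrix imaging analysis of brain-like tissue, as one
tested pipeline: from simulated 32-frame polarimetric acquisitions to
physically screened Mueller images, polarimetric purity and anisotropy
maps, three decomposition families, per-region statistics, and grey/white
-matter classification.

## Who this is for

Mueller-matrix imaging measures the full 4×4 polarization transfer matrix
of a sample per pixel. In brain tissue, the derived scalars — depolarization
Δ, retardance R, diattenuation D — separate grey matter (GM) from
myelinated white matter (WM) and expose fiber orientation, which makes the
technique a candidate label-free guide for neurosurgery. This package is
for researchers who want a complete, reproducible reference implementation
of that analysis chain, runnable end to end with no measured data: a
synthetic phantom generator emulates a six-specimen, twenty-region study at
the six acquisition wavelengths (450, 500, 550, 590, 650, 680 nm),
including the 550 nm depolarization dip and specimen-to-specimen
variability.

## The analysis

- **Acquisition** (`muellermap.acquisition`) — forward instrument model
  I = PSA·M·PSG with a rotating-quarter-wave PSG (4 states) and an 8-row
  analyzer (sliding quarter-wave retarder × 4-orientation micropolarizer
  camera): 32 frames per Mueller measurement; least-squares reconstruction
  M = pinv(PSA)·I·inv(PSG).
- **Realizability** (`muellermap.realizability`) — ensemble criterion:
  the Cloude coherency H(M) = ¼ Σ M_ij σ_i⊗σ_j* must be positive
  semi-definite and the passivity conditions M00(1+‖D‖) ≤ 1,
  M00(1+‖P‖) ≤ 1 must hold (tol 1e-5). Failing pixels are masked, never
  repaired.
- **Purity/anisotropy** (`muellermap.purity`) — indices of polarimetric
  purity P1 ≤ P2 ≤ P3 from the coherency eigenvalues, degree of purity
  P_Δ, and linear/circular anisotropy coefficients α_L, α_C.
- **Forward polar decomposition** (`muellermap.polar`) — Lu–Chipman
  M = M_Δ·M_R·M_D with maps Δ = 1 − |tr m_Δ|/3, R = arccos(tr M_R/2 − 1),
  D = ‖D‖, plus the linear-retardance axis
  θ = ½·atan2(M_LR(3,1) − M_LR(1,3), M_LR(2,3) − M_LR(3,2)).
- **Symmetric decomposition** (`muellermap.symmetric`) — five-layer
  M = M_D2·M_R2·M_Δd·M_R1ᵀ·M_D1 with a strictly diagonal depolarizer and a
  gauge-free total retarder.
- **Differential decomposition** (`muellermap.differential`) — L = ln M
  split into G-antisymmetric (six mean spectroscopic properties) and
  G-symmetric (three fluctuation variances, three covariances) parts.
- **Classification** (`muellermap.classify`) — class-balanced KNN under
  leave-one-specimen-out cross-validation, permutation feature importance,
  floating sequential feature selection, Mann–Whitney separability tests.
- **Phantom** (`muellermap.phantom`) — the synthetic study generator;
  `muellermap.pipeline` orchestrates all stages.

See `docs/methods.md` for the model details, conventions, parameter
defaults, and known limitations.

## Worked example

```python
import numpy as np
import muellermap as mm

# compose a tissue-like pixel: depolarizer . retarder . diattenuator
m = (mm.diagonal_depolarizer(0.25, 0.25, 0.25)      # depolarization 0.75
     @ mm.linear_retarder(0.42, np.deg2rad(30))     # WM-like retardance
     @ mm.linear_diattenuator(0.02, np.deg2rad(30)))

print(mm.ensemble_criterion(m, reflectance=0.5).passed)
res = mm.lu_chipman(m)
print(f"Delta={res.delta_total:.3f}  R={res.retardance:.3f} rad  "
      f"D={res.diattenuation:.3f}")
MLR, _, _, _ = mm.retarder_split(res.M_R)
print(f"axis theta = {np.rad2deg(mm.retardance_axis(MLR)):.1f} deg")
print(f"P_Delta = {mm.ipps(m).P_delta:.3f}")
```

prints

```
True
Delta=0.750  R=0.420 rad  D=0.020
axis theta = 30.0 deg
P_Delta = 0.250
```

i.e. the decomposition recovers the composed depolarization, retardance,
diattenuation, and fast-axis orientation exactly, the pixel is physically
realizable at a 0.5 reflectance scale, and its degree of polarimetric
purity is low, as expected for a strongly depolarizing medium.

The numbered scripts under `analysis/` run the full study:
`01_simulate_study.py` (the 120-cube phantom campaign and acquisition
bookkeeping), `02_screen_realizability.py` (clean vs corrupted
acquisitions), `03_decompose.py` (all three decompositions with region
statistics), `04_classify.py` (the eight KNN models, importance, feature
selection, rank tests). Each writes its tables under `results/`.

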