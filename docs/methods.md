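# Methods

`muellermap` implements a complete multispectral Mueller-matrix imaging
analysis of brain-like tissue: a forward instrument model and least-squares
reconstruction, pixel-wise physical-realizability screening, polarimetric
purity and anisotropy maps, three decomposition families (forward polar,
symmetric, differential), per-region statistics, and grey/white-matter (GM/WM)
classification — driven end to end by a synthetic phantom generator that
emulates a six-specimen, twenty-region, six-wavelength study.

## Conventions

Stokes vectors are (I, Q, U, V) with Q = horizontal − vertical; indices are
0-based throughout, and "element (i, j)" means row i, column j of the 4×4
matrix. Angles are radians; the linear-retardance fast axis θ lives in
(−π/2, π/2]. Mueller matrices are stored unnormalized where the intensity
scale matters (passivity) and normalized (m00 = 1) inside the decompositions.
The canonical elements (retarder, rotator, diattenuator, depolarizer) follow
the Lu–Chipman sign conventions, so the half-angle arctangent
θ = ½·atan2(M(3,1) − M(1,3), M(2,3) − M(3,2)) recovers a factory retarder's
axis exactly, quadrant included.

## Instrument model and reconstruction

The polarization state generator (PSG) is a horizontal polarizer followed by
a quarter-wave plate at the four angles ±15.12°, ±51.69° (the classic
condition-number-optimal set for a rotating-quarter-wave generator; the
matrix's condition number is reported on the instrument object). The
analyzer (PSA) has eight rows: a slide-in quarter-wave retarder at 45°
(out/in) in front of a four-orientation micropolarizer camera
(0°/45°/90°/135°), giving 8 × 4 = 32 intensity frames per Mueller
measurement and therefore 3 840 frames / 120 matrices for six filters and
twenty regions. Reconstruction is per-pixel least squares,
M = pinv(PSA) · I · inv(PSG), which reduces to the exact two-sided inverse
when the analyzer is square. Negative noiseless intensities (possible for
deliberately unphysical test matrices) are clamped at zero and counted
rather than raised, since near-singular matrices can graze zero.

## Realizability screening

A matrix is accepted when (1) the Cloude coherency matrix
H = ¼ Σ M_ij σ_i ⊗ σ_j* is positive semi-definite and (2) the forward and
reverse passivity conditions M00(1 + ‖D‖) ≤ 1 and M00(1 + ‖P‖) ≤ 1 hold,
all at tolerance 1e-5. The eigenvalue tolerance is relative to trace(H), so
the verdict does not depend on the overall intensity scale. For cubes that
store normalized matrices, a scene-reflectance scale (default 0.5)
multiplies the stored M00 inside the passivity test; this keeps passivity
meaningful for normalized data while still catching anomalously bright
pixels (saturated specular patches reconstruct to matrices whose scaled M00
overflows the gain limit — this is exactly how the corruption tests fail
the screen). Failing pixels are excluded from all downstream statistics,
never repaired.

## Purity and anisotropy

With trace-normalized coherency eigenvalues λ̂0 ≥ … ≥ λ̂3, the indices of
polarimetric purity are P1 = λ̂0 − λ̂1, P2 = λ̂0 + λ̂1 − 2λ̂2,
P3 = 1 − 4λ̂3, and the degree of polarimetric purity is
P_Δ = sqrt((2P1² + (2/3)P2² + (1/3)P3²)/3). Small negative eigenvalues
(within tolerance) are clipped before normalization.

The anisotropy coefficients are built from the vectors k, r, q of the 3×3
block and Σ = 3(1 − ‖k‖²) + 2·D·P − 2·r·q:

    α_L = sqrt(s1² + s2²)/sqrt(Σ),  α_C = s3/sqrt(Σ),
    s_i = sqrt((D_i + P_i)² + (r_i − q_i)²).

Two typographic ambiguities in the printed formulas were resolved by
requiring internal consistency: the denominator uses sqrt(Σ) (plain Σ makes
the coefficients unbounded for weak pure retarders), and the α_L numerator
is one radical over the sum of squares (the summed-radical reading yields
P_α up to 1.35 on pure matrices). Under the implemented form every
nontrivial pure matrix saturates P_α = 1 exactly.

**Known limitation.** The chain P_α ≤ P_Δ ≤ 1 is *not* a theorem under
this normalization. It holds with equality on pure matrices and exactly on
diattenuator mixtures, but retarder-type depolarization can push P_α
slightly above P_Δ; the closed-form counterexample
m = diag(1, 0.64, 0.8, 0.8) · retarder(π/2) gives P_α = 0.813 against
P_Δ = 0.750, and the worst excess observed over large random physical
ensembles is ≈ 0.12. The implementation keeps this normalization
and documents the excess instead of silently capping the coefficient.

## Forward polar (Lu–Chipman) decomposition

M = M_Δ · M_R · M_D. The diattenuator is the rank-one-plus-isotropic form
built from the first-row diattenuation vector; M′ = m · M_D⁻¹; the
depolarizer block is the signed symmetric square root of m′m′ᵀ (sign from
det m′, ties broken by the symmetric eigendecomposition with descending
eigenvalues); M_R = M_Δ⁻¹ · M′, re-projected onto the nearest proper
rotation so the retarder block stays orthogonal even for ill-conditioned
depolarizers (exact for clean inputs; the ideal depolarizer falls back to
the orthogonal Procrustes projection of m′). Scalars: Δ = 1 − |tr m_Δ|/3,
R = arccos(tr M_R/2 − 1), D = ‖D‖. Diattenuation within 1e-9 of unity is
clipped and flagged. The retarder is further split as M_R = M_LR · M_ψ with
2ψ = atan2(b01 − b10, b00 + b11) of the 3×3 block — degenerate only at
R = π, where the split is reported but flagged ambiguous.

## Symmetric decomposition

M = M_D2 · M_R2 · M_Δd · M_R1ᵀ · M_D1 with a strictly diagonal depolarizer.
Applicability is checked through the eigensystem of N = G·Mᵀ·G·M (real,
nonnegative eigenvalues with a full eigenvector set). The diattenuation
vectors come from the eigenvector of the largest eigenvalue of Mᵀ·G·M·G and
M·G·Mᵀ·G respectively, scaled to first Stokes component one; in degenerate
(pure retarder) cases the eigenvector with the largest first component is
taken, so the diattenuators collapse to the identity. The intermediate
matrix M′ = M_D2⁻¹·M·M_D1⁻¹ is factored by SVD with both orthogonal frames
forced to proper rotations; any reflection moves into the sign of d3, and
the singular values are reported in descending magnitude. The total
retarder is computed as M_R2 · M_R1ᵀ, which is invariant to the common
rotation gauge of the SVD and reproduces a pure-retarder input exactly (the
transposed ordering gives the inverse rotation with the same trace, hence
the same R).

## Differential decomposition

L = ln M via the principal matrix logarithm; pixels with eigenvalues on the
closed negative real axis are excluded and counted rather than
branch-shifted (any branch choice changes retardances by 2π). The Minkowski
split L = Lm + Lu uses G = diag(1, −1, −1, −1). The six means read off the
Lm template; the fluctuation statistics read off Lu as

    a = Lu11 − Lu00, b = Lu22 − Lu00, c = Lu33 − Lu00
    var_LH = a − b − c, var_L45 = b − a − c, var_C = c − a − b
    cov(LH, L45) = 2·Lu12, cov(LH, C) = −2·Lu13, cov(L45, C) = −2·Lu23.

These constants follow from the Gaussian fluctuation model of the
birefringence generators and are pinned by an independent Monte-Carlo
oracle (`gaussian_fluctuation_medium`, a closed-form Rodrigues ensemble
average that never touches the log machinery): at 1e5 draws the recovered
variances agree with the configured ones to within 5%, covariance signs
included. Applicability is the positive semi-definiteness of the coherency
transform of the trace-removed G-symmetric part, which equals the
requirement that the implied fluctuation covariance structure is valid.
All quantities are per single traversal (path length z = 1). Per-wavelength
summaries aggregate the masked pixels by the mean (switchable to median).

## Classification protocol

Features are Δ, R, D per wavelength (18 features). The table is balanced
once globally by uniform random removal to the smallest (specimen × class)
cell. KNN with Euclidean distance on z-scored features (scaler fitted per
fold's training split; without scaling, Δ ∈ [0,1] and R ∈ [0,π] would be
incommensurate — the scaling is switchable). Cross-validation leaves one
specimen out per fold, so the training fraction is (k−1)/k = 83% for six
specimens. Default neighbor counts: 50 (single-wavelength), 8
(all-features), 48 (selected-features). Metrics are accuracy and the
true-GM/true-WM rates from the predicted-by-expected confusion matrix.

Permutation importance shuffles one feature of the held-out specimen s = 10
times per feature and fold and reports the mean accuracy decrease. Floating
sequential selection (forward and backward) uses a nested
leave-one-specimen-out accuracy over the fold's training specimens as its
objective, on a subsampled table for tractability; once a feature is
removed it is never revisited. A training-set-accuracy objective is
available but not the default: for KNN it is structurally biased toward
noise features (each training point is its own nearest neighbor, so adding
an uninformative dimension isolates points and inflates in-sample
accuracy).

Distribution separability uses the two-sided Mann–Whitney U test
(tie-corrected; identical samples return p = 1).

## Synthetic phantom

Each region is an elliptical specimen with a cortical GM field, a branching
WM core built from a random tree of segments, and one or two thin
sinusoidal vessels, on a diffuse support-plate background (a strong
isotropic depolarizer, Δ = 0.95 — deliberately inside the physical cone so
that measurement noise never unmasks background pixels, whereas a pure
boundary state such as the identity would fail the eigenvalue condition
under any perturbation). Per pixel, M(λ) = isotropic depolarizer(1 − Δ) ·
linear retarder(R, θ) · linear diattenuator(D, θ), so the forward polar
decomposition inverts the generator exactly (noiseless recovery to 1e-6)
and every pixel passes the ensemble criterion by construction. The axis
field varies smoothly in space and rotates by 0.05 rad per wavelength step,
exercising the axis-map analysis.

The class curves are anchored to the measured trends: GM depolarization
0.60 → 0.88 and WM 0.885 → 0.945 across 450–680 nm, with a 550 nm dip of
9% (GM) and 2% (WM) below the 500/590 nm trend line (the hemoglobin
signature, imposed phenomenologically; vessels dip 12%); GM retardance
0.16 → 0.32 rad and WM 0.42 → 0.72 rad; diattenuation below 0.04 with GM
about half of WM.

Within-class variability follows a single-latent-axis model: one smooth
"myelination" field per region, of SD 0.27 in units of the GM→WM gap,
drives every parameter at every wavelength; each channel adds independent
measurement noise (Δ: 0.080 → 0.060 across wavelengths; R: 0.18 → 0.40;
D: 0.012 → 0.018). Because all three parameters are noisy monotone channels
of the same latent, R and D carry essentially no class information beyond
the (better-measured) Δ channels — which is what makes depolarization the
dominant feature for selection and importance, as in measured brain data —
while every channel keeps the anchored marginal distributions.
Specimen effects are multiplicative lognormal factors per (parameter,
class): a coherent component (σ = 0.015 for Δ, 0.18 for R, 0.15 for D —
retardance and diattenuation depend on fiber orientation relative to the
view and vary far more between specimens) plus per-wavelength jitter
(0.03/0.06/0.05), and additional per-region factors (0.02/0.20/0.20)
reflecting how same-class structures differ between views. These are the
axes that leave-one-specimen-out cross-validation must generalize across.

What the phantom does **not** model: photon transport (the 550 nm dip and
all spectral trends are imposed, not emulated from absorption spectra),
anatomically faithful geometry, the 7° oblique detection geometry,
polarizance distinct from diattenuation, and spatially varying M00.
Passing tests on the phantom therefore demonstrate the correctness of the
analysis chain and the qualitative reproduction of the study's
classification structure, not quantitative agreement with any measured
tissue values.

## Problem sizes and determinism

The default study is 6 specimens × 20 regions at 64 × 64 pixels and six
wavelengths; classification tables are capped at 2 000 rows per
(specimen × class) cell (800 for permutation importance, 1 500 for the
selection objective) — sizes chosen so a full study runs in minutes on one
core. Round-trip suites use 1 000 seeded random compositions per
decomposition family; invariant ensembles use 10 000 random physical
matrices; the fluctuation Monte Carlo uses 1e5 draws. One master seed
drives phantom geometry, specimen effects, balancing, shuffles, and noise;
identical (config, seed) pairs reproduce every output bit for bit.

The two directional classification checks (all-wavelength model strictly
above every single-wavelength model; the selection picking the three
short-wavelength depolarization features in ≥ 4 of 6 folds) are properties
of a stochastic study and sit close to their thresholds under the default
conditions: across seeds the selection check passes on roughly half the
study draws and the margin of the all-wavelength model over the best
single-wavelength model ranges from about −3 to +1.5 accuracy points.
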