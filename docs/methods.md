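# Methods

## Scope and model overview

`beamtune` solves the beam-model commissioning inverse problem: recover the
primary-electron-beam parameters P = (E, σ_E, s, α) of a linac simulator
from water-phantom dose profiles. The package couples

1. a **virtual linac** (`beamtune.surrogate`) that maps P and a field size
   to a 3D dose distribution,
2. **profile machinery** (`beamtune.profiles`) mirroring clinical dosimetry
   conventions,
3. two **regressors** (`beamtune.pca` + `beamtune.svr`, and
   `beamtune.deep`) that invert profiles to P, and
4. a **refinement stage** (`beamtune.reconstruct`) that polishes the
   regression estimate by matching observed profiles against profiles
   reconstructed from grid-interpolated PCA features.

## The virtual linac

A full radiation-transport simulation of the study design takes months of
CPU; the surrogate replaces it with a smooth, separable parametric model

    D(x, y, z) = d(z) · ℓ(x, z) · ℓ(y, z)

evaluated at the voxel centres x, y ∈ {−24.75 + 0.5 i} cm,
z ∈ {0.25 + 0.5 k} cm (i, k = 0..99) of a 50 cm water cube at SSD 100 cm.
It is explicitly *not* transport physics: its constants are chosen once for
physical plausibility of 6 MV beams, and its purpose is to make parameter
recovery meaningful and testable, not to be dosimetrically faithful.

**Depth dose** d(z) = (1 − e^(−βz)) e^(−μz) with μ = (0.30/E)(1 − 0.04
ln(field/10)) cm⁻¹ and β solved numerically so the maximum sits at
D_max = 1.4 cm. At E = 6.0 MeV and 10×10 cm² this gives ≈ 65% depth dose at
10 cm; harder beams (larger E) penetrate deeper, larger fields add phantom
scatter. σ_E enters only through a deliberately tiny attenuation term
10⁻⁴·σ_E cm⁻¹: over the training ranges the profile change from a full σ_E
sweep is more than an order of magnitude below that from a full E sweep
(asserted as a test property). This mirrors the physical fact — and the
motivating observation — that the spectrum width barely shapes dose
profiles, so σ_E is essentially unidentifiable from them.

**Lateral profiles** are double-error-function field edges with geometric
half-width w(z) = (field/2)(1 + z/100) and Gaussian penumbra width

    σ_p(z) = 0.22 + 0.50·s·(1 + z/50) + 0.02·α·(1 + z/100) + 0.003·z  [cm]

plus an in-field "horn" term (1 + A u² e^(−u⁴)), u = x/w, with amplitude
A = (0.10·(7 − E) + 0.04·α)·√(field/10)·e^(−z/30), and additive scatter
wings (0.003 + 0.012·α)·√(field/10)·e^(−max(|x|−w,0)/3) outside the edge.
The curve is normalized to exactly 1 on the axis. Rationale for the
constants:

* the base penumbra 0.22 cm reflects source occlusion plus the blur that
  the 0.5 cm tally pitch and finite chamber volume impose — a 6 MV 80–20
  penumbra is several millimetres, and nothing sharper than the voxel
  pitch is representable in the tallied data anyway;
* the focal-spot coefficient 0.5 is the geometric projection of the spot
  through a ≈ 50 cm collimator aperture onto the phantom;
* divergence acts mainly on in-field flatness and on the out-of-field
  scatter wings — its dominant effects on real large-field profiles — and
  only weakly on the edge gradient;
* horns grow with field size, soften with energy and wash out with depth.

Each of E, s and α thereby owns a distinct, super-noise signature (depth
falloff + horn level; edge width; flatness + wings), which is what makes
the inverse problem well posed for these three parameters.

**Noise.** Monte Carlo tally uncertainty is emulated as multiplicative
Gaussian noise with SD 0.75% of local dose per voxel (2 SD = 1.5%), seeded
per (tuple, field) via `numpy` seed sequences spawned from the master seed.

**What the surrogate does not emulate:** electron contamination in the
build-up region, off-axis spectrum softening beyond the parametric horn,
collimator transmission structure, detector-specific response, asymmetric
or elliptical focal spots, and any correlated (non-white) tally noise.
Consequently, passing tests demonstrate that the *pipeline* — extraction,
feature learning, regression, refinement — is correct and self-consistent;
they do not certify accuracy on any particular physical accelerator, whose
profile-to-parameter sensitivities may be weaker or correlated differently.

## Study design

* Training grid S: E ∈ {5.6, 5.8, 6.0, 6.2, 6.4} MeV, σ_E ∈ {0, 0.5, 1}
  MeV, s ∈ {0, 0.1, 0.2, 0.3, 0.4} cm, α ∈ {0, 1, 2, 3}° — 300 tuples,
  node order lexicographic with E slowest (an ordering the data files and
  feature tables depend on; chosen once and kept).
* Test tuples are drawn uniformly **without replacement** (an assumption:
  the sampling scheme is otherwise unspecified) from candidate sets offset
  from the grid values (12 × 8 × 4 × 8 = 3072 candidates), so every test
  beam differs from every training node in all four coordinates.
* Default profile selection: depth, lateral at D_max, lateral at 10 cm
  depth, for the 10×10 and 30×30 fields; 1 mm sampling; lateral cuts are
  the mean of the x- and y-direction cuts (circular spot symmetry; can be
  disabled).
* Dose grids are normalized to 100% at the trilinearly interpolated
  on-axis dose at 1.4 cm. The lattice has no voxel on the axis, so "axis"
  means bilinear interpolation among the four central columns.
* Measured profiles carry no absolute normalization, so a convention is
  declared: depth profiles are scaled to 100 at their refined (parabolic)
  maximum, and each lateral profile is anchored so its centre equals the
  normalized depth dose at its depth (same-field depth profile preferred,
  any depth profile otherwise, an explicit fallback value as last resort).

## PCA + SVR

Per profile index, a mean-centred PCA (full SVD) keeps k = 3 components,
sign-fixed so each component's largest-magnitude coordinate is positive
(PCA signs are arbitrary; persistence must be stable). Features are
z-scored over training nodes before regression — rbf-kernel SVR is
scale-sensitive — with the scaler stored in the model file. Targets are
standardized per parameter and de-standardized at prediction. The CV search
grid is C ∈ {1, 10, 100, 1000}, ε ∈ {10⁻⁴…10⁻¹} (standardized-target
units), γ ∈ scale-heuristic × {0.1, 1, 10}; fivefold CV with seeded fold
assignment; ties resolved by first-found minimum, making selection
deterministic. Predictions are clipped into the hypercube H (flagged), so
they are always valid refinement start points.

## Deep model

The multi-encoder CNN follows a fixed architectural contract: per profile
of length N, L = ⌊log₂N/3⌋ blocks of [conv(k=3) → ReLU → conv(k=3) → ReLU →
maxpool(2)] with 16·2^(b−1) filters in block b, a closing unit-size-filter
convolution, flattening, concatenation over profiles, dense 100 → dense 100
(ReLU) → linear 4. Convolutions are length-preserving (zero padding), so
only pooling shrinks the sequence and the encoder output length is N ∕ 2^L
(integer division), never below 3. "int" in the depth formula is floor.

Because no deep-learning framework is part of the dependency set, the
layers, backward passes and the Adam optimizer are implemented directly in
numpy (float32, im2col convolutions); the gradient is verified against
finite differences in the test suite. Training: MSE on z-scored targets,
constant learning rate 10⁻⁴, 300 epochs, batch size 32, seeded 20%
validation split, best-validation-loss checkpoint restored ("best model"
is otherwise undefined). Inputs are centred on the training mean shape and
scaled by one scalar SD per profile index — a conditioning choice that
preserves the relative weighting of penumbra versus flat regions.
Single-threaded training is bit-reproducible for a fixed seed.

With only 300 training samples the CNN generalizes more coarsely than the
PCA + SVR route (its validation loss plateaus within ~20 epochs); both
serve as start points for the refinement stage, which drives them to
virtually identical final estimates.

## Refinement

Multilinear interpolation over the rectilinear grid (nodal-exact,
continuous, cheap) turns the per-node PCA features into feature fields;
singleton axes are held fixed. The objective Σ wᵢ‖Profᵢ − RecProfᵢ(P)‖² is
therefore piecewise-smooth with gradient kinks at cell boundaries;
minimization uses SLSQP in per-axis normalized coordinates (bounds [0,1],
forward-difference step 10⁻⁶ of each axis span, ftol 10⁻¹², ≤ 200
iterations per pass). Three safeguards address the kinks and the very flat
σ_E valley: a seeded 5-point multi-start (the start point plus
±1-grid-step perturbations, clipped), restart-polishing of each start
(SLSQP rerun at its own result until the objective stops improving, which
resets the quasi-Newton state once the iterate settles inside one smooth
cell), and a final finer-step polish of the winner. All weights default
to 1. The returned
optimum never scores worse than the start; optimizer failure returns the
start point flagged, never raises. A σ_E policy freezes that coordinate
when configured (e.g. 0.50 MeV for measured data, where it is
unidentifiable).

## Evaluation metrics

* Predicted-vs-true comparison: per-parameter OLS of predicted on true
  (slope, intercept, Pearson r, R²) and the SD of true − predicted with the
  sample (n−1) convention.
* Mean absolute profile error in percentage points of the D_max dose
  (profile units; the alternative — % of local dose — is available by
  dividing out the reference, but the global convention is the default).
* 1D gamma index: global normalization (tolerance anchored to the 100%
  D_max dose; local mode behind a flag), evaluated profile resampled at
  0.1 mm inside a ±3·DTA window — beyond it the distance term alone
  exceeds 1, so the window is exact, as the oracle comparison test checks.

## Problem sizes used by the tests

The suite runs the full 300-node design at 1 mm profile resolution for the
PCA/SVR/refinement checks, and a 2 mm resolution (N ≈ 248 per profile) for
CNN training — the package's chosen desk-scale operating point for the deep
model, keeping a 300-epoch run to a few minutes on one CPU. The 25-tuple
test pool, noise level and grid are the default study conditions
throughout.

## Known limitations

* σ_E is by construction (and physically) unrecoverable from profiles; its
  predictions are reported but meaningless, and should be frozen when
  tuning real data.
* The refinement can only be as good as the PCA reconstruction: features
  interpolated between grid nodes inherit the rank-3 truncation and the
  multilinear facet error, so refined estimates are not guaranteed to beat
  the raw regression when the regression is already at noise level.
* Everything downstream of the surrogate is limited by the 0.5 cm tally
  pitch: build-up curvature and sub-voxel penumbra structure are not
  representable in the extracted profiles.
* The dose text format is self-defined; data exported by other simulators
  need a reader adapter.
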