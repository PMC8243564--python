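# beamtune

Estimate the primary-electron-beam parameters of a medical linear
accelerator's Monte Carlo model from water-phantom dose profiles.

## The problem

Monte Carlo simulation of a megavolt photon beam starts with the electron
beam striking the bremsstrahlung target. That beam is characterized by four
numbers that are unique to each machine and not directly measurable in a
clinic:

* **E** — mean electron energy (MeV),
* **σ_E** — FWHM of the (Gaussian) energy spectrum (MeV),
* **s** — focal-spot FWHM (cm),
* **α** — angular divergence (degrees).

Commissioning a simulator therefore means solving an inverse problem: given
percentage-depth-dose and lateral dose profiles measured in a water phantom,
find the (E, σ_E, s, α) whose simulated profiles match them. `beamtune`
implements a machine-learned, two-stage solution plus a parametric virtual
linac that generates the training and test data, so every stage runs and is
tested at desk scale.

## Method

**Training data.** Dose grids D(x, y, z) are produced on a 100³ lattice of
0.5 cm voxels (50 cm water cube, SSD 100 cm) for every tuple of a regular
grid *S* of 300 parameter tuples — 5 energies × 3 spectrum widths × 5 spot
sizes × 4 divergences — for square fields of 3, 10 and 30 cm. Each grid is
normalized to 100% at the on-axis dose maximum (D_max = 1.4 cm), and a
user-selected set of profiles Prof₁…Prof_n is extracted at 1 mm resolution
(default: depth profile, lateral at D_max and lateral at 10 cm depth, for
the 10×10 and 30×30 fields).

**Stage 1 — regression.** Two interchangeable regressors give an initial
estimate P_PRED = (E, σ_E, s, α):

* *PCA + SVR*: a per-profile PCA extracts three shape features F_{i,1..3}
  (the leading three components explain ≥ 98% of shape variance); four
  independent rbf-kernel support-vector regressors map the concatenated 3n
  features to the four parameters, with (C, ε, γ) chosen by fivefold
  cross-validation.
* *Deep model*: a multi-input 1D CNN — one convolutional encoder per
  profile (L = ⌊log₂N/3⌋ blocks of two kernel-3 convolutions + max-pooling,
  16, 32, 64, … filters, closed by a unit-size filter), concatenated and
  fed through two dense ReLU layers of width 100 into a linear 4-output
  head — trained 300 epochs with Adam (lr 10⁻⁴) on MSE, best validation
  checkpoint kept. (Implemented in numpy with hand-derived backpropagation;
  no deep-learning framework required.)

**Stage 2 — reconstruction-based refinement.** The PCA features form fields
over the 4D grid *S*; multilinear interpolation gives features — and via the
inverse PCA transform, reconstructed profiles RecProf_i(P) — at any P in the
bounding hypercube *H*. The final estimate solves

    P_MIN = argmin_{P ∈ H}  Σᵢ wᵢ ‖Profᵢ − RecProfᵢ(P)‖²

with SLSQP from the start point P_PRED (seeded multi-start, bounds = *H*).
Fit quality is reported per profile as mean absolute error (% of the D_max
dose) and the 1D gamma pass rate (3% / 3 mm, global normalization).

σ_E barely shapes the dose profiles (on real machines as in the surrogate),
so it is not recoverable; a config policy can freeze it (e.g. at 0.50 MeV).

## Worked example

`python examples/quickstart.py` trains PCA + SVR models on a reduced
12-node grid and tunes a beam from six synthetic "measured" profiles
generated at a tuple the models never saw:

```
true beam:  E=6.15  s=0.18  alpha=2.2
P_PRED:     E=6.151  s=0.181  alpha=2.212
P_MIN:      E=6.132  s=0.192  alpha=2.096
 f10_depth:  MAE 0.11%  gamma 3%/3mm pass 100.0%
f10_lat1.4:  MAE 0.10%  gamma 3%/3mm pass 100.0%
 f10_lat10:  MAE 0.08%  gamma 3%/3mm pass 100.0%
 f30_depth:  MAE 0.11%  gamma 3%/3mm pass 100.0%
f30_lat1.4:  MAE 0.21%  gamma 3%/3mm pass 100.0%
 f30_lat10:  MAE 0.13%  gamma 3%/3mm pass 100.0%
```

The regression already lands within ~0.002 MeV / 0.003 cm / 0.015° of the
true beam; the refinement stage then matches the reconstructed profiles to
the observed ones to ≲ 0.2% mean absolute error with full gamma pass rates.

The same workflow is available from the shell:

```
beamtune fit-pca   --config config.yaml
beamtune train-svr --config config.yaml        # or: beamtune train-dl
beamtune tune      --config config.yaml --fix-sigma-e 0.5 measured/*.txt
beamtune gamma reference.txt evaluated.txt
```

Measured profiles are plain two-column text files with a small `# key:
value` header (see `beamtune.profiles.read_measured_profile`).

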