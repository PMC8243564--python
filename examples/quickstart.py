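"""Tune a beam from (synthetic) measured profiles with a reduced grid.

Trains the PCA + SVR models on a 12-node training grid, then estimates the
beam parameters behind six "measured" profiles generated at a beam the
models never saw.
"""

from beamtune import RunConfig, BeamParameters
from beamtune.pipeline import (
    build_training_data, fit_pca_models, profile_sets_for_tuples, tune_beam,
)
from beamtune.svr import train_svr

config = RunConfig(
    grid_axes=((5.6, 6.0, 6.4), (0.5,), (0.0, 0.4), (0.0, 3.0)),
    seed=0,
)
training = build_training_data(config)          # 12 tuples x 2 fields
pca_models = fit_pca_models(training)           # one shape model per profile
bundle = train_svr(pca_models, training.grid, seed=config.seed)

truth = BeamParameters(E=6.15, sigma_E=0.5, s=0.18, alpha=2.2)
measured = profile_sets_for_tuples(config, [truth], seed_offset=99)[0]

result = tune_beam(config, pca_models, bundle, measured, grid=training.grid)
print(f"true beam:  E={truth.E}  s={truth.s}  alpha={truth.alpha}")
p = result.start
print(f"P_PRED:     E={p.E:.3f}  s={p.s:.3f}  alpha={p.alpha:.3f}")
p = result.optimum
print(f"P_MIN:      E={p.E:.3f}  s={p.s:.3f}  alpha={p.alpha:.3f}")
for row in result.per_profile:
    print(f"{row['profile']:>10}:  MAE {row['mae_pct']:.2f}%  "
          f"gamma 3%/3mm pass {row['gamma_pass_rate_pct']:.1f}%")
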