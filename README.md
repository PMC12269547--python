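# diffpoint

Pointwise inference of protein diffusive properties along single-particle
trajectories.

Single-molecule tracking yields noisy 2-D coordinate series `x(t), y(t)`
of 20–200 frames.  Classical analysis fits one diffusion coefficient per
trajectory from mean-square displacements, which breaks down when a
protein switches behaviour mid-track — binding to DNA, entering a
compartment, dimerising, or changing its degree of directedness.
`diffpoint` instead labels **every frame** with the generalised
diffusion coefficient `K` (pixels²/frameᵅ), the anomalous exponent `α`,
and a discrete motion state `s` (0 immobile, 1 confined, 2 free,
3 directed), and then detects the changepoints where any of them jump.

Motion is modelled as piecewise fractional Brownian motion with
`MSD(t) = 4 K t^α` and Hurst exponent `H = α/2`.  The pipeline is:

1. **simulate** — labelled trajectories from five biological scenarios
   (single-state, Markov multi-state, quenched traps, transient
   confinement, dimerisation), with exact Davies–Harte fractional
   Gaussian noise;
2. **features** — ten per-frame time-series features (normalised
   coordinates, step lengths, turning angle, straightness measures,
   log-difference series);
3. **net** — one bidirectional-LSTM sequence labeller per output
   variable (three skip-connected, layer-normalised biLSTM blocks,
   ~514 k parameters), trained with masked per-trajectory losses — MAE
   for α, MAE in `log₁₀(K+1)` space for K, class-weighted NLL for the
   state;
4. **postprocess** — plateau merging, median filtering, minimum state
   dwell, then exact penalized-L2 (PELT) changepoint detection on the
   min-max-normalised predictions and a window-5 merge of the
   per-variable changepoint sets around the K anchors;
5. **evaluate** — MAE / MALE, row-normalised confusion matrices, and
   changepoint Jaccard / RMSE after tolerance-gated Hungarian pairing.

The network implementation is pure NumPy with hand-derived gradients, so
everything runs (and is tested) on a CPU.  See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
import numpy as np
from diffpoint import SimConfig, simulate_two_segment, compute_features
from diffpoint.simulate import build_dataset
from diffpoint.nn import TrainConfig, train
from diffpoint.nn.predict import predict_batch
from diffpoint.postprocess import detect_changepoints

# a trajectory whose diffusivity jumps at frame 100
traj, labels = simulate_two_segment((1.0, 1.0), (1.0, 30.0), T=200,
                                    rng=np.random.default_rng(0))
print(labels.changepoints)          # -> [100]

# train a small K model and look for that jump in the prediction
ds = build_dataset(total=400, seed=3, recipe=[("SSM", {"T_range": (20, 40)}),
                                              ("MSM", {"T_range": (20, 40)})])
result = train(ds, "K", TrainConfig(max_epochs=3, seed=0))
logK_hat = predict_batch(result.model, [traj])[0]
print(logK_hat[:100].mean(), logK_hat[100:].mean())
print(detect_changepoints(logK_hat=logK_hat, variables=("K",))["merged"])
```

With these exact seeds the predicted `log₁₀(K+1)` series averages 0.38
over the first segment and 1.73 over the second — the 30-fold jump in K
is clearly recovered pointwise even by this one-minute training run —
and the detector prints `[56 91 108]`: a boundary near the true frame
100 plus spurious points, because a model this small still wiggles
(longer training, as in `scripts/acceptance.py`, sharpens both).  The
`examples/` directory has one short narrative
script per capability (simulation, features, training, changepoint
detection, metrics); each prints the numbers it computes and one line on
what they mean.

A thin CLI wraps the same API:

```bash
diffpoint simulate --out data/ --total 2000 --seed 7
diffpoint train --data data/manifest.yaml --variable alpha --out alpha.npz
diffpoint predict --data data/trajectories.csv --checkpoint alpha.npz \
    --out pred.csv --cp-out cps.csv --cp-vars alpha
diffpoint evaluate --data data/manifest.yaml --predictions pred.csv \
    --changepoints cps.csv --out metrics.json
```

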