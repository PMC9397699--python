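# chaolle

Chaotic-dynamics features for two-class motor-imagery EEG: largest
Lyapunov exponents over optimized phase-space reconstructions, tuned by
chaotic metaheuristics, classified with a generalized-RBF soft-margin SVM.

## The problem

Imagining opening the hand versus making a fist desynchronizes the
sensorimotor alpha rhythm (ERD, 8–13 Hz over C3/CP5) and changes the
complexity of the ongoing EEG. The largest Lyapunov exponent γ₁ — the
average exponential divergence rate of nearby phase-space trajectories —
quantifies that complexity: γ₁ > 0 marks chaos, γ₁ ≈ 0 a limit cycle,
γ₁ < 0 a stable (damped) regime. Estimating γ₁ from a scalar EEG epoch
requires reconstructing the attractor by delay embedding, which in turn
needs a time lag ζ (chosen at the first minimum of the lagged mutual
information) and an embedding dimension n (chosen where the false-
nearest-neighbor fraction vanishes). Both searches are capped by ceilings
— traditionally max lag 10 and max dimension 3 — and those ceilings
matter: if the MI minimum lies beyond the lag ceiling the reconstruction
is cramped and the features lose class information.

`chaolle` treats the two ceilings, separately per class
(θ = max-lag/max-dim for "open" and for "fist"), as free parameters and
tunes them with population metaheuristics under a hard 10,000-evaluation
budget:

* **TW** — Tug-of-War: candidate "teams" weighted affinely by fitness
  onto [1, 2] pull each other toward better regions, with a geometrically
  decaying random perturbation;
* **CTW** — chaotic Tug-of-War: the perturbation stream comes from a
  1-D chaotic map (twelve provided: logistic, tent, Chebyshev, …),
  trading stochastic sampling for ergodic, non-repeating iterates;
* **WD** — Intelligent Water Drops: a layered-graph swarm in which drops
  prefer low-soil edges and erode soil locally and along the
  iteration-best path.

Features go through a paired t-test screen and into a soft-margin SVM
with the generalized RBF kernel `K(x,z) = exp(−‖x−z‖^τ / (2σ^τ))`
(width σ, shape τ ∈ (0,2], center c), trained on repeated stratified
70/25/5 splits. At τ = 2 this is exactly the standard Gaussian kernel.

Because no public recordings accompany the task, the package ships a
first-class synthetic generator: canonical chaotic systems with
independently known exponents (Jacobian / Benettin oracles) for
validating the estimator, and labeled two-class ERD/ERS epochs whose
classes differ in alpha power (ERD depth) and chaoticity (logistic-map
component with r = 3.9 vs 3.6).

## Worked example

```python
import numpy as np
from chaolle import (ChaoticSystemSpec, ERDConfig, PipelineConfig,
                     delay_embed, generate_erd_epochs, run_offline)
from chaolle.lyapunov import divergence_curve, largest_lyapunov
from chaolle.synthetic import simulate_map_series

# 1. the exponent estimator against an analytic oracle
x = simulate_map_series(ChaoticSystemSpec("logistic", n_samples=5100,
                                          transient_discard=100,
                                          initial_state=[0.2]))
curve = divergence_curve(delay_embed(x, lag=1, dim=2), theiler=1,
                         max_steps=50)
print(largest_lyapunov(curve).lle)
# 0.6936057019221508            (analytic value: ln 2 = 0.6931)

# 2. traditional vs optimized pipelines on planted-effect epochs
epochs = generate_erd_epochs(ERDConfig(n_epochs_per_class=200, seed=1000))
trad = run_offline(PipelineConfig(method="traditional", seed=0,
                                  n_repeats=20), epochs)
ctw = run_offline(PipelineConfig(method="ctw", seed=0, n_repeats=20,
                                 max_evaluations=500,
                                 fitness_epochs_per_class=24), epochs)
print(trad.mean_accuracy, ctw.mean_accuracy)
# 0.75375 0.8266666666666665
```

The first number recovers the logistic map's exponent ln 2 to 0.1%: the
divergence curve of the reconstructed attractor grows at 0.694 nats per
iteration before saturating. The second pair shows the point of the
package: on epochs whose alpha quarter-period (~12 samples at 512 Hz)
exceeds the traditional lag ceiling of 10, held-out accuracy rises from
0.75 to 0.83 once the chaotic Tug-of-War search frees the ceilings —
the optimizer only ever sees the training partition, and accuracy is
measured on epochs it never touched.

A command-line interface covers the same ground:

```
chaolle simulate --system logistic --r 4 --n 5000 --out series.csv
chaolle make-epochs --n-per-class 100 --seed 7 --out epochs.h5
chaolle optimize --method ctw --map logistic --benchmark rastrigin --seed 7
chaolle run --epochs epochs.h5 --method ctw --seed 7 --out report/
```

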