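# eghr — multi-context blind source separation with the error-gated Hebbian rule

Blind source separation (BSS) asks a listener to recover statistically
independent hidden signals `s` from linear mixtures `x = A s` without
knowing the mixing weights `A` — the cocktail-party problem.  In a
*multi-context* BSS task the mixing changes with context: `x = A(k) s` for
context `k = 1..C`, or even continuously in time, `A(t) = A0 + A1 R(t)`.
Conventional ICA algorithms relearn their unmixing matrix at every context
switch and, because they update multiplicatively, can never compress
high-dimensional inputs.

This package implements, tests and analyses a biologically plausible
alternative: a linear network `u = W x` trained by the three-factor
**error-gated Hebbian rule (EGHR)**

    ΔW ∝ ⟨ (E0 − E(u)) · g(u) · xᵀ ⟩,     E(u) = Σᵢ −log p0(uᵢ),  g = dE/du,

the stochastic gradient descent of the cost `L = ⟨(E(u) − E0)²⟩ / 2`.  The
scalar "global factor" `E(u)` gates plasticity between Hebbian
(`E < E0`) and anti-Hebbian (`E > E0`); the threshold
`E0 = ⟨−log p0(s)⟩ + 1` calibrates converged outputs to the unit source
scale.  Given redundant inputs (`N_x ≥ C·N_s`), the rule finds one synaptic
matrix `W` that separates **all** experienced contexts simultaneously
(`W A(k) = Ω(k)`, a signed permutation, for every `k`), retains them
without further updates, filters out time-varying mixing components
(`W A1 = O`), and generalizes to unseen context vectors.

The library ships:

- `eghr.sources` / `eghr.mixing` — unit-Laplace and synthetic song-like
  source generators; static, per-context, rotating, Ornstein–Uhlenbeck,
  Markov-switching and context-vector mixing regimes;
- `eghr.rule` — the EGHR update, cost, `E0` calibration and training loop;
- `eghr.metrics` — the transform matrix `K = W A`, the BSS error (mean
  second-to-first ratio over rows and columns of `|K|`), Frobenius
  overlaps, signed-permutation matching, trajectory PCA;
- `eghr.theory` — existence of multi-context solutions (full column rank
  of `(A(1), …, A(C))`), an explicit SVD construction of
  `W(A0, A1) = (Ω, O)`, and the linear-stability coefficients
  (`Φii > −1`, `Φij Φji > 1`);
- `eghr.baselines` — natural-gradient, non-holonomic and ICA-mixture
  updates, plus the row-space test showing why they cannot reduce
  dimensionality;
- `eghr.experiments` / `eghr.cli` — config-driven reproductions of the
  five experiment protocols at native or scaled size.

## Worked example

Two contexts mix two unit-Laplace sources into six sensory inputs through
different random matrices; one network learns both:

```python
import numpy as np
from eghr import *

prior = laplace_prior()
A1 = sample_mixing_matrix(6, 2, seed=0)
A2 = sample_mixing_matrix(6, 2, seed=1)
mixing = MixingModel(kind="per_context", matrices=(A1, A2))
schedule = make_context_schedule(2, 40, 500, mode="alternating")
net = init_network(n_u=2, n_x=6, seed=0)
cfg = TrainConfig(eta=1e-3, batch_size=100, n_steps=20_000, record_every=500)
final, traj = train_eghr(net, laplace_sampler(2), mixing, schedule, prior, cfg)

for k, A in enumerate((A1, A2), start=1):
    K = transform_matrix(final.W, A)
    print(f"context {k}: BSS error = {bss_error(K).total:.4f}")
    print(np.array_str(K, precision=3, suppress_small=True))
```

prints

```
context 1: BSS error = 0.0075
[[-0.009  0.994]
 [-1.002 -0.006]]
context 2: BSS error = 0.0036
[[0.004 1.008]
 [0.997 0.004]]
```

Both transform matrices `K(k) = W A(k)` are signed permutations to within
one percent: each output encodes exactly one source in *both* contexts
(here with a sign flip in context 1), so the BSS error — 0 for a perfect
one-to-one mapping, up to 1 for total confusion — is below 0.01.  The
existence check `multicontext_solution_exists([A1, A2])` confirms the
concatenated block has full column rank 4, the capacity condition
`N_x = 6 ≥ C·N_s = 4`.

The same experiments are available from the shell:

```sh
eghr run two_context --seed 3 --out results/
eghr report results/
eghr fixtures list
```

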