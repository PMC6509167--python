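# Methods

## Model

Hidden sources `s ∈ R^{N_s}` are independent, zero-mean, unit-variance and
non-Gaussian; the default generator draws them i.i.d. in time from the
unit Laplace density `p(s) = (1/√2) exp(−√2|s|)`.  Sensory inputs are
linear mixtures `x = A s` with `A` of shape `(N_x, N_s)` and `N_x ≥ N_s`
(undercomplete sensing).  Contexts change `A`: discretely
(`A(k)`, `k = 1..C`, switching at session boundaries), continuously
(`A(t) = A0 + A1 R(t)` with a slow driver `R`), or through a context
vector (`A(v) = A0 + Σ_k A(k) v_k`).

A single-layer linear network `u = W x` learns with the error-gated
Hebbian rule

    ΔW = η ⟨ (E0 − E(u)) g(u) xᵀ ⟩,   E(u) = Σᵢ −log p0(uᵢ),   g = dE/du,

the gradient descent of `L = ⟨(E(u) − E0)²⟩/2`.  For the unit-Laplace
prior, `−log p0(u) = √2|u| + ½ln2` and `g(u) = √2·sign(u)` (subgradient 0
at `u = 0`, a measure-zero event, keeping the update odd-symmetric).
Separation of all contexts is equivalent to
`W (A(1),…,A(C)) = (Ω(1),…,Ω(C))` with each `Ω` a signed permutation;
such a `W` exists iff the concatenated block has full column rank, hence
generically iff `N_x ≥ C·N_s` and `N_u ≥ N_s`.

### Output-scale calibration

`E0 = N_u (1 + ½ln2) + 1` ("auto") equates the converged output scale
with the unit source scale; the trainer verifies this empirically (output
variances within 10% of 1 after convergence in the unit tests).  The `+1`
is the calibration constant on top of the summed per-unit entropy; `E0`
is computed from `N_u` because the agent knows only its own output
dimension.

### Stability

Linear stability of a separating fixed point is governed by the
source/prior coefficients

    Φii = cov[−log p0(sᵢ), g′(sᵢ) sᵢ²],
    Φij = cov[−log p0(sᵢ), g′(sᵢ)]·⟨sⱼ²⟩ + cov[−log p0(sⱼ), sⱼ²]·⟨g′(sᵢ)⟩,

stable iff `Φii > −1` and `Φij Φji > 1`.  The bare `sⱼ²` and `g′(sᵢ)`
factors in `Φij` are interpreted as expectations — the covariances
already consume the paired variables; this reading reproduces the
stability observed in every converged run.  For the matched unit-Laplace
pair, `g′` is distributional (`2√2 δ(s)`); the Monte-Carlo estimator
replaces `sign(u)` with `tanh(u/β)` and extrapolates `β → 0` linearly
over `β ∈ {0.1, 0.03, 0.01}` (a Richardson-style treatment), recovering
the analytic limit `(Φii, Φij) = (0, 2)` — stable.  The matched Gaussian
pair gives `(1, 1)`: marginal, as rotational symmetry demands.

## Training loop

The expectation `⟨·⟩` is realised as a minibatch mean (default batch
100); `batch_size = 1` recovers the pure online rule, and a batch rate
`η = B·η_online` matches the online rule over the same number of consumed
samples.  All learning rates below are quoted online.  Metrics (cost on a
fresh evaluation batch, per-context BSS error, component overlaps
`|W A|_F`, `W` snapshots) are recorded every `record_every` steps and at
step 0, so session-start errors are visible.  Training aborts on
non-finite or exploding `W` (max|entry| > 1e6); there is no clipping.
Double precision throughout; every random draw flows from explicit seeds.

## Experiment protocols

Native dimensions, learning rates, session structures and ω values are
the protocols' published values; batch sizes, run lengths of scaled runs
and the specific scaled dimensions are this package's choices, frozen
once and documented here.

- **two_context** — `N_s = N_u = 2`, `N_x = 6`, two alternating contexts,
  `η = 4×10⁻⁶`.  The published protocol leaves the session length open; we
  use 100 sessions × 10⁵ samples.  Some seeds transit a slow ICA saddle
  (a scaled-rotation `K`) and need ~40 sessions to escape; 100 gives
  margin.  Memory retention is asserted from the third re-exposure
  onward: the first re-exposure still carries geometric interference
  from the intervening context and its start error depends on the random
  matrix draw.
- **hundred_context** — native `C = 100`, `N_s = N_u = 10`,
  `N_x = 2000`, `η = 10⁻⁵`, 600 random sessions × 10⁵ samples.  The
  scaled variant used by the acceptance checks is `C = 10`,
  `N_s = N_u = 4`, `N_x = 80`, 1200 sessions × 2.5×10⁴ samples at
  `η = 2×10⁻⁶`; the lower rate shrinks the stochastic fluctuation of the
  dominant `|K|` entries around 1 at this smaller size.
- **rotating** — `A(t) = A0 + A1 R(ωt)` with `ω = √2π/100` rad/s.  The
  time unit of ω is left open; we adopt the convention of the
  moving-source protocol (rates in rad/s, 4410 Hz sampling), giving
  ~10⁻⁵ rad per sample.  In this quasi-static regime the learning
  dynamics reliably converge to the time-invariant solution
  (`W A1 → O`).  At much faster rotation the phase-averaged cost also
  has a mirror attractor (`W A0 → O`, outputs follow `R(t)s`) and a
  rank-one compromise state, and convergence becomes draw-dependent.
  Training is two-phase, 2×10⁵ batch steps at `η = 10⁻⁵` then the same
  at `η/5`: the first phase selects the basin, the second lowers the
  noise floor of the overlap `|W A1|_F`.  The OU variant drives each
  entry of `R` with an Ornstein–Uhlenbeck process (`τ = 10⁻³`,
  Euler–Maruyama with per-sample `dt = 10⁻⁶`, so τ spans 10³ samples;
  stationary mean 0, variance 1 — amplitude is a free
  parameter, fixed at 1 here).
- **songlike_moving** — two synthetic song-like sources at 4410 Hz mixed
  through `A0 + A1 R(θ(t))` where the angular velocity switches among
  `{−0.1π, 0, 0.1π}` rad/s with per-sample redraw probability 1/8820
  (per-step uniform redraw, possibly to the same value), `η = 10⁻⁷`,
  2.65×10⁷ samples.
- **context_vector_generalization** — native `N_s = N_u = 10`,
  `N_x = 100`, four zero-sum context components, the canonical ten
  training vectors, `η = 2×10⁻⁷`, 120 sessions.  The scaled acceptance
  variant is `N_x = 40`, `N_s = N_u = 4`, two components, ten evenly
  spaced training vectors on the 1-simplex, Laplace sources,
  `η = 5×10⁻⁶`, 300 sessions × 2.5×10⁴ samples; 20 test vectors are
  drawn uniformly from `[0,1]ⁿ` and normalised to sum 1.  With the
  zero-sum construction (`A0` = mean of the drawn matrices,
  `A(k)` = deviation from it) the components carry no common feature, so
  generalization must come from `W ⊥ A(k)`.

`ExperimentConfig.scale` shrinks `N_x`, the context count and the run
length proportionally; runs that would violate `N_x ≥ C·N_s` refuse to
start.

## Synthetic song-like sources

`make_songlike_sources` stands in for recorded birdsong: each source is
an amplitude-modulated three-harmonic chirp with a distinct fundamental,
syllable-like gaps, optional additive white Laplace noise, normalised
row-wise to zero mean and unit variance.  It reproduces the features the
learning rule cares about — temporal structure, super-Gaussian amplitude
statistics, near-independence between sources (|correlation| < 0.1) —
but none of the spectro-temporal detail of real song, spatial acoustics,
or microphone geometry.  Tests passing on these sources therefore
demonstrate the algorithmic claims, not performance on real audio.

## Numerical choices

- BSS error: per column, the ratio of the second-largest to largest
  |K| entry (rows analogously); total = Σcol/(2N_s) + Σrow/(2N_u) ∈
  [0, 1].  Argmax ties break to the lowest index; an all-zero row or
  column scores 1, so dead outputs are penalised rather than undefined;
  a 1×1 K scores 0 (no competitor).  Multi-context summaries weight
  contexts equally.
- Rank tests threshold singular values at 1e-10 × the largest;
  `row_space_preserved` exposes its own relative tolerance.
- The reference solution `W = Ω V0 S⁻¹ Uᵀ` is built from the thin SVD of
  `(A0, A1)`; any orthogonal `X` with `XU = I` yields the same product
  `W(A0, A1)`, which the constructor verifies to 1e-8 on every call.
- Signed-permutation matching is greedy on the globally largest
  remaining |K| entry — adequate for near-converged K, not an optimal
  assignment in general.
- The ICA-mixture responsibilities use the standard mixture likelihood
  `z_k ∝ |det W^k| Π p0((W^k x)ᵢ)`, which the update law alone does not
  fix; inference uses the highest-responsibility model.  The
  infomax algorithm is represented by the natural-gradient update, with
  which it shares fixed points and stability.
- Trajectory CSVs are written with 17 significant digits and read back
  with round-trip float parsing, so write→read is lossless; `W`
  snapshots travel in an `.npz` sidecar.

## Known limitations

- Convergence times of the alternating two-context task vary strongly
  with the random mixing draw (slow saddles); the defaults carry margin
  but pathological draws may need more sessions.
- The fast-rotation regime (ω of order one per sample) is genuinely
  multistable under this rule; the package documents and avoids it
  rather than solving it.
- Only the unit-Laplace (and reference Gaussian) priors ship; `PriorModel`
  is the extension point, and `default_E0` requires an analytic per-unit
  entropy or an explicitly supplied `E0`.
- Baseline algorithms are implemented exactly as quoted update laws, not
  as the full machinery of their original publications (no bias terms or
  adaptive source densities in the ICA mixture).
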