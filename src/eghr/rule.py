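"""The error-gated Hebbian rule (EGHR): outputs, global factor, cost,
update step, and the training loop.

Model
-----
Linear outputs u = W x with W an (N_u, N_x) synaptic matrix.  A scalar
"global factor" E(u) = sum_i -log p0(u_i) gates plasticity:

    dW  propto  < (E0 - E(u)) g(u) x^T >,      g(u) = dE/du,

which is Hebbian while E(u) < E0 and anti-Hebbian above the threshold.
The rule is the stochastic gradient descent of L = <(E(u) - E0)^2>/2, the
cost for statistical dependency among outputs.  The threshold
E0 = <-log p0(s)> + 1 calibrates the converged output scale to the source
scale (unit variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mixing import ContextSchedule, MixingModel
from .metrics import bss_error, frobenius_overlap, transform_matrix
from .priors import PriorModel

__all__ = [
    "NetworkState",
    "TrainConfig",
    "TrainTrajectory",
    "outputs",
    "global_factor",
    "default_E0",
    "eghr_cost",
    "eghr_step",
    "init_network",
    "train_eghr",
]

_DIVERGENCE_LIMIT = 1.0e6


@dataclass
class NetworkState:
    """Synaptic strengths plus bookkeeping for reproducible training."""

    W: np.ndarray  # (N_u, N_x)
    step: int = 0
    rng_seed: int = 0

    @property
    def n_u(self) -> int:
        return self.W.shape[0]

    @property
    def n_x(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``eta`` is the learning rate applied to the minibatch-mean update; with
    ``batch_size`` B this matches the online rule at rate eta/B over the
    same number of consumed samples, so published online rates translate
    as eta = B * eta_online.  ``E0="auto"`` uses the calibrated default with
    n = N_u (the agent knows only its own output dimension).
    """

    eta: float
    batch_size: int = 100
    n_steps: int = 10_000
    record_every: int = 100
    E0: float | str = "auto"
    eval_batch_size: int = 2000

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.batch_size < 1 or self.n_steps < 1:
            raise ValueError("batch_size and n_steps must be positive")
        if self.record_every < 1 or self.record_every > self.n_steps:
            raise ValueError("need 1 <= record_every <= n_steps")


@dataclass
class TrainTrajectory:
    """Periodic records of the network during training.

    ``bss_error_per_context`` has one column per tracked mixing matrix
    (one per context for per-context mixing; the instantaneous A(t) for
    time-varying mixing).  ``overlaps`` holds |W A^(c)|_F per tracked
    component matrix.
    """

    times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    cost: np.ndarray = field(default_factory=lambda: np.empty(0))
    bss_error_per_context: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    overlaps: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    overlap_names: tuple[str, ...] = ()
    W_snapshots: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 0)))

    def __len__(self) -> int:
        return len(self.times)


def outputs(W: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Neural outputs u = W x (column-wise for batches)."""
    W = np.asarray(W)
    x = np.asarray(x)
    if x.shape[0] != W.shape[1]:
        raise ValueError(
            f"input dimension {x.shape[0]} does not match W columns {W.shape[1]}"
        )
    return W @ x


def global_factor(u: np.ndarray, prior: PriorModel) -> np.ndarray:
    """E(u) = sum_i -log p0(u_i); for a batch, one value per column."""
    return prior.neg_log_density(np.asarray(u)).sum(axis=0)


def default_E0(prior: PriorModel, n_sources: int) -> float:
    """Calibrated threshold E0 = n * <-log p0(s)> + 1.

    With this E0, the converged outputs match the (unit-variance) source
    scale.  For the unit Laplace prior the per-unit entropy is
    1 + (1/2) ln 2.
    """
    if n_sources < 0:
        raise ValueError("n_sources must be non-negative")
    if prior.per_unit_entropy is None:
        raise ValueError(
            f"prior {prior.name!r} has no analytic per-unit entropy; estimate "
            "<-log p0(s)> by Monte Carlo and pass E0 explicitly"
        )
    return n_sources * prior.per_unit_entropy + 1.0


def eghr_cost(U: np.ndarray, prior: PriorModel, E0: float) -> float:
    """L = <(E(u) - E0)^2>/2 over the columns of the output batch."""
    U = np.atleast_2d(np.asarray(U))
    if U.shape[1] == 0:
        raise ValueError("batch must be non-empty")
    e = global_factor(U, prior)
    return float(np.mean((e - E0) ** 2) / 2.0)


def eghr_step(
    W: np.ndarray,
    X: np.ndarray,
    prior: PriorModel,
    E0: float,
    eta: float,
) -> np.ndarray:
    """One minibatch update W' = W + eta * <(E0 - E(u)) g(u) x^T>.

    The expectation is the mean over the columns of ``X``; a single-column
    batch recovers the pure online rule.  Pure function: no hidden state.
    """
    W = np.asarray(W, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == 0:
        raise ValueError("batch must be non-empty")
    U = outputs(W, X)
    gate = E0 - global_factor(U, prior)  # (T,)
    G = prior.g(U)  # (N_u, T)
    dW = (G * gate) @ X.T / X.shape[1]
    W_new = W + eta * dW
    if not np.all(np.isfinite(W_new)):
        raise FloatingPointError(
            "non-finite synaptic update (diverging W); reduce eta"
        )
    return W_new


def init_network(
    n_u: int, n_x: int, seed: int = 0, scale: float = 0.1
) -> NetworkState:
    """Random initial state, W entries i.i.d. N(0, scale^2)."""
    if n_u < 1 or n_x < 1:
        raise ValueError("dimensions must be positive")
    if n_u > n_x:
        warnings.warn(
            f"n_u={n_u} > n_x={n_x}: overcomplete output layer; source "
            "recovery is not guaranteed",
            stacklevel=2,
        )
    if scale == 0:
        warnings.warn("scale=0 gives a zero initial W (degenerate)", stacklevel=2)
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, scale, size=(n_u, n_x))
    return NetworkState(W=W, step=0, rng_seed=seed)


def _resolve_E0(cfg: TrainConfig, prior: PriorModel, n_u: int) -> float:
    if isinstance(cfg.E0, str):
        if cfg.E0 != "auto":
            raise ValueError(f"E0 must be a number or 'auto', got {cfg.E0!r}")
        return default_E0(prior, n_u)
    return float(cfg.E0)


def _metric_matrices(
    mixing: MixingModel, t_sample: int
) -> tuple[list[np.ndarray], list[np.ndarray], tuple[str, ...]]:
    """(matrices for BSS error, matrices for overlaps, overlap names)."""
    if mixing.kind == "time_varying":
        a_now = mixing.matrix_at(min(t_sample, mixing.r_traj.shape[0] - 1))
        comps = [mixing.matrices[0], mixing.a1]
        return [a_now], comps, ("A0", "A1")
    mats = list(mixing.matrices)
    names = tuple(f"A{k + 1}" if mixing.kind == "per_context" else "A0"
                  for k in range(len(mats)))
    return mats, mats, names


def train_eghr(
    net: NetworkState,
    source_sampler,
    mixing: MixingModel,
    schedule: ContextSchedule | None,
    prior: PriorModel,
    cfg: TrainConfig,
) -> tuple[NetworkState, TrainTrajectory]:
    """Train the network on freshly sampled source/input batches.

    ``source_sampler(n, rng)`` must return an (N_s, n) array of source
    samples.  Contexts follow ``schedule`` (in units of batch steps) for
    per-context mixing; time-varying mixing advances its R trajectory by
    ``batch_size`` samples per step, applying the per-sample A(t) inside
    each batch.  Metrics are recorded every ``record_every`` steps on a
    fresh evaluation batch (never the training batch).
    """
    if mixing.kind == "per_context" and schedule is None:
        raise ValueError("per_context mixing requires a ContextSchedule")
    W = np.array(net.W, dtype=float)
    rng = np.random.default_rng(net.rng_seed)
    eval_rng = np.random.default_rng(np.random.SeedSequence([net.rng_seed, 2**20]))
    E0 = _resolve_E0(cfg, prior, net.n_u)
    B = cfg.batch_size

    times, costs, bss_rows, ov_rows, snaps = [], [], [], [], []
    overlap_names: tuple[str, ...] = ()

    def record(step: int) -> None:
        nonlocal overlap_names
        if mixing.kind == "time_varying":
            # index at whichever resolution the R trajectory uses
            r_index = step * B if mixing.r_traj.shape[0] >= cfg.n_steps * B else step
        else:
            r_index = 0
        bss_mats, ov_mats, overlap_names = _metric_matrices(mixing, r_index)
        bss_rows.append([bss_error(transform_matrix(W, a)).total for a in bss_mats])
        ov_rows.append([frobenius_overlap(W, a) for a in ov_mats])
        # fresh evaluation batch for the cost, never the training batch
        s_eval = source_sampler(cfg.eval_batch_size, eval_rng)
        if mixing.kind == "time_varying":
            a_eval = bss_mats[0]
        elif mixing.kind == "per_context":
            a_eval = mixing.matrices[schedule.context_at_step(step) - 1]
        else:
            a_eval = mixing.matrices[0]
        costs.append(eghr_cost(outputs(W, a_eval @ s_eval), prior, E0))
        times.append(step)
        snaps.append(W.copy())

    record(0)  # the untrained state, so session-1 starts are visible
    for step in range(cfg.n_steps):
        s = source_sampler(B, rng)
        t_sample = step * B
        if mixing.kind == "static":
            x = mixing.matrices[0] @ s
        elif mixing.kind == "per_context":
            k = schedule.context_at_step(step)
            x = mixing.matrices[k - 1] @ s
        else:
            # time_varying: a per-sample R trajectory (length >= n_steps * B)
            # is applied inside the batch; a per-step trajectory (length >=
            # n_steps) holds R fixed within each batch, which is equivalent
            # whenever R moves negligibly over one batch
            if mixing.r_traj.shape[0] >= cfg.n_steps * B:
                sl = mixing.r_traj[t_sample : t_sample + B]
                rs = np.einsum("trs,st->rt", sl, s)
            elif mixing.r_traj.shape[0] >= cfg.n_steps:
                rs = mixing.r_traj[step] @ s
            else:
                raise ValueError(
                    "R trajectory must cover n_steps (per-step) or "
                    "n_steps * batch_size (per-sample) entries"
                )
            x = mixing.matrices[0] @ s + mixing.a1 @ rs
        W = eghr_step(W, x, prior, E0, cfg.eta)
        if np.max(np.abs(W)) > _DIVERGENCE_LIMIT:
            raise FloatingPointError(
                f"training diverged at step {step} (eta={cfg.eta}): "
                f"max|W| > {_DIVERGENCE_LIMIT:g}"
            )
        if (step + 1) % cfg.record_every == 0 or step == cfg.n_steps - 1:
            record(step + 1)

    traj = TrainTrajectory(
        times=np.asarray(times, dtype=int),
        cost=np.asarray(costs),
        bss_error_per_context=np.asarray(bss_rows),
        overlaps=np.asarray(ov_rows),
        overlap_names=overlap_names,
        W_snapshots=np.asarray(snaps),
    )
    final = NetworkState(W=W, step=net.step + cfg.n_steps, rng_seed=net.rng_seed)
    return final, traj
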