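"""Mixing-matrix regimes: static multi-context, rotating, OU-driven,
Markov-switching and context-vector mixing, plus the mixing operation itself.

The generative model is x(t) = A s(t) where A is an ``(N_x, N_s)`` mixing
matrix that may depend on a discrete context index k, x = A^(k) s, or on
time through a low-dimensional driver, A(t) = A^(0) + A^(1) R(t), or on a
context vector v, A(v) = A^(0) + sum_k A^(k) v_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MixingModel",
    "ContextSchedule",
    "sample_mixing_matrix",
    "make_context_schedule",
    "rotation_matrix",
    "ou_matrix_process",
    "markov_switching_omega",
    "time_varying_mixing",
    "context_vector_mixing",
    "zero_sum_context_components",
    "mix",
]


@dataclass(frozen=True)
class MixingModel:
    """A static, per-context, or time-indexed source-to-input map.

    kind = "static":       ``matrices`` holds one (N_x, N_s) matrix.
    kind = "per_context":  ``matrices`` holds one matrix per context
                           (index k-1 for context k).
    kind = "time_varying": A(t) = A0 + A1 @ R_traj[t]; ``matrices`` holds
                           the time-invariant A0, and ``a1``/``r_traj``
                           hold the time-variant part.
    """

    kind: Literal["static", "per_context", "time_varying"]
    matrices: tuple[np.ndarray, ...]
    a1: np.ndarray | None = None
    r_traj: np.ndarray | None = None  # (T, N_R, N_s)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.matrices}
        if len(shapes) != 1:
            raise ValueError(f"all mixing matrices must share a shape, got {shapes}")
        if self.kind == "time_varying":
            if self.a1 is None or self.r_traj is None:
                raise ValueError("time_varying mixing requires a1 and r_traj")

    @property
    def n_x(self) -> int:
        return self.matrices[0].shape[0]

    @property
    def n_s(self) -> int:
        return self.matrices[0].shape[1]

    @property
    def n_contexts(self) -> int:
        return len(self.matrices)

    def stacked(self) -> np.ndarray:
        """Horizontal concatenation (A^(1), ..., A^(C)) for rank tests."""
        return np.hstack(self.matrices)

    def matrix_at(self, t: int) -> np.ndarray:
        """A(t) for a time-varying model (A^(0) + A^(1) R(t))."""
        if self.kind != "time_varying":
            raise ValueError("matrix_at is only defined for time_varying mixing")
        return self.matrices[0] + self.a1 @ self.r_traj[t]


@dataclass(frozen=True)
class ContextSchedule:
    """Which context generates the inputs in each session."""

    context_of_session: np.ndarray  # 1-based context indices
    session_length: int
    mode: Literal["alternating", "uniform_random"]

    def __post_init__(self) -> None:
        if self.session_length < 1:
            raise ValueError("session_length must be >= 1")
        c = np.asarray(self.context_of_session)
        if c.size and c.min() < 1:
            raise ValueError("context indices are 1-based")

    @property
    def n_sessions(self) -> int:
        return len(self.context_of_session)

    def context_at_step(self, t: int) -> int:
        return int(self.context_of_session[(t // self.session_length) % self.n_sessions])


def sample_mixing_matrix(
    n_x: int, n_s: int, seed: int, scale: float = 1.0
) -> np.ndarray:
    """Random (N_x, N_s) mixing matrix with i.i.d. N(0, scale^2) entries.

    Requires n_x >= n_s (undercomplete sensing: at least as many inputs as
    sources) and guarantees full column rank, resampling on the
    measure-zero failure.
    """
    if n_s < 1 or n_x < n_s:
        raise ValueError(
            f"need n_x >= n_s >= 1 for a full-column-rank mixing matrix, "
            f"got n_x={n_x}, n_s={n_s}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(100):
        a = rng.normal(0.0, scale, size=(n_x, n_s))
        if np.linalg.matrix_rank(a) == n_s:
            return a
    raise RuntimeError("failed to draw a full-column-rank mixing matrix")


def make_context_schedule(
    n_contexts: int,
    n_sessions: int,
    session_length: int,
    mode: str = "alternating",
    seed: int | None = None,
) -> ContextSchedule:
    """Build a session-level context schedule.

    ``alternating`` cycles 1, 2, ..., C, 1, 2, ...; ``uniform_random`` draws
    each session's context uniformly from {1, ..., C}.
    """
    if n_contexts < 1:
        raise ValueError("n_contexts must be >= 1")
    if mode == "alternating":
        contexts = (np.arange(n_sessions) % n_contexts) + 1
    elif mode == "uniform_random":
        rng = np.random.default_rng(seed)
        contexts = rng.integers(1, n_contexts + 1, size=n_sessions)
    else:
        raise ValueError(f"unknown schedule mode {mode!r}")
    return ContextSchedule(
        context_of_session=contexts, session_length=session_length, mode=mode
    )


def rotation_matrix(angle: float) -> np.ndarray:
    """2x2 rotation (cos t, -sin t; sin t, cos t)."""
    if not np.isfinite(angle):
        raise ValueError("angle must be finite")
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def ou_matrix_process(
    rows: int,
    cols: int,
    tau: float,
    n_steps: int,
    dt: float,
    seed: int,
) -> np.ndarray:
    """Entrywise Ornstein-Uhlenbeck trajectory of a (rows, cols) matrix.

    Each entry independently follows dR = -(R/tau) dt + sqrt(2/tau) dB,
    which has stationary mean 0 and stationary variance 1, discretised by
    Euler-Maruyama.  Returns an array of shape ``(n_steps, rows, cols)``
    started from the stationary distribution.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    if dt >= tau:
        raise ValueError(
            f"Euler-Maruyama requires dt < tau, got dt={dt}, tau={tau}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty((n_steps, rows, cols))
    out[0] = rng.normal(size=(rows, cols))  # stationary init
    decay = 1.0 - dt / tau
    noise_sd = np.sqrt(2.0 * dt / tau)
    for t in range(1, n_steps):
        out[t] = decay * out[t - 1] + noise_sd * rng.normal(size=(rows, cols))
    return out


def markov_switching_omega(
    n_steps: int,
    omegas: Sequence[float] | None = None,
    p_switch: float = 1.0 / 8820.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-step angular frequency held constant except for rare redraws.

    At every step, with probability ``p_switch`` the value is redrawn
    uniformly from ``omegas`` (possibly landing on the current value),
    otherwise it is held.  Defaults: omegas = (-0.1 pi, 0, 0.1 pi) rad/s
    and p_switch = 1/8820 per step.
    """
    if omegas is None:
        omegas = (-0.1 * np.pi, 0.0, 0.1 * np.pi)
    omegas = np.asarray(omegas, dtype=float)
    if omegas.size == 0:
        raise ValueError("omegas must be non-empty")
    if not 0.0 <= p_switch <= 1.0:
        raise ValueError("p_switch must be a probability")
    rng = np.random.default_rng(seed)
    # draw all potential redraw values and switch flags vectorised
    choices = rng.integers(0, omegas.size, size=n_steps)
    switch = rng.random(n_steps) < p_switch
    switch[0] = True  # initial draw
    # index of the most recent switch at every step
    last = np.maximum.accumulate(np.where(switch, np.arange(n_steps), -1))
    return omegas[choices[last]]


def time_varying_mixing(
    a0: np.ndarray, a1: np.ndarray, r_traj: np.ndarray
) -> MixingModel:
    """A(t) = A^(0) + A^(1) R(t) with a precomputed R trajectory.

    ``r_traj`` has shape (T, N_R, N_s); A^(0) is (N_x, N_s) and A^(1) is
    (N_x, N_R).
    """
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    r_traj = np.asarray(r_traj, dtype=float)
    if r_traj.ndim != 3:
        raise ValueError("r_traj must be a (T, N_R, N_s) stack of matrices")
    n_x, n_s = a0.shape
    if a1.shape[0] != n_x or r_traj.shape[1] != a1.shape[1] or r_traj.shape[2] != n_s:
        raise ValueError(
            f"incompatible shapes: A0 {a0.shape}, A1 {a1.shape}, "
            f"R(t) {r_traj.shape[1:]}"
        )
    return MixingModel(kind="time_varying", matrices=(a0,), a1=a1, r_traj=r_traj)


def context_vector_mixing(
    a0: np.ndarray, deps: Sequence[np.ndarray], v: Sequence[float]
) -> np.ndarray:
    """A(v) = A^(0) + sum_k A^(k) v_k for a context vector v."""
    a0 = np.asarray(a0, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(deps) != v.size:
        raise ValueError(
            f"context vector length {v.size} != number of components {len(deps)}"
        )
    out = a0.copy()
    for ak, vk in zip(deps, v):
        ak = np.asarray(ak)
        if ak.shape != a0.shape:
            raise ValueError("all context components must share A^(0)'s shape")
        out += vk * ak
    return out


def zero_sum_context_components(
    n_x: int, n_s: int, seed: int, n_components: int = 4, scale: float = 1.0
) -> tuple[np.ndarray, ...]:
    """Context-component family (A^(0), A^(1), ..., A^(n)) summing to zero.

    Draws n random matrices Â^(k), sets A^(0) to their mean and
    A^(k) = Â^(k) - A^(0).  By construction sum_k A^(k) = O, so the
    context-dependent components carry no feature common to all contexts:
    the common part lives entirely in A^(0).  Setting v to the k-th basis
    vector recovers Â^(k) exactly, and the uniform v = (1/n, ..., 1/n)
    recovers A^(0).
    """
    if n_x < n_s:
        raise ValueError(f"need n_x >= n_s, got n_x={n_x}, n_s={n_s}")
    rng = np.random.default_rng(seed)
    hats = [rng.normal(0.0, scale, size=(n_x, n_s)) for _ in range(n_components)]
    a0 = np.mean(hats, axis=0)
    comps = [h - a0 for h in hats]
    return (a0, *comps)


def mix(
    model: MixingModel,
    sources: "np.ndarray | object",
    schedule: ContextSchedule | None = None,
) -> np.ndarray:
    """Apply the mixing model column-wise: x(t) = A^(k(t)) s(t) or A(t) s(t).

    ``sources`` may be a SourceBatch or a bare (N_s, T) array.  For
    per-context mixing a schedule is required; for time-varying mixing the
    stored R trajectory must cover all T steps.
    """
    s = getattr(sources, "values", sources)
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != model.n_s:
        raise ValueError(
            f"sources must be (N_s={model.n_s}, T), got shape {s.shape}"
        )
    t_total = s.shape[1]
    if model.kind == "static":
        return model.matrices[0] @ s
    if model.kind == "per_context":
        if schedule is None:
            raise ValueError("per_context mixing requires a ContextSchedule")
        x = np.empty((model.n_x, t_total))
        for t0 in range(0, t_total, schedule.session_length):
            t1 = min(t0 + schedule.session_length, t_total)
            k = schedule.context_at_step(t0)
            x[:, t0:t1] = model.matrices[k - 1] @ s[:, t0:t1]
        return x
    # time_varying: x_t = A0 s_t + A1 (R_t s_t), vectorised over t
    if model.r_traj.shape[0] < t_total:
        raise ValueError(
            f"R trajectory covers {model.r_traj.shape[0]} steps < T={t_total}"
        )
    rs = np.einsum("trs,st->rt", model.r_traj[:t_total], s)
    return model.matrices[0] @ s + model.a1 @ rs
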