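"""Conventional ICA algorithms used as points of contrast.

The natural-gradient and non-holonomic algorithms update W multiplicatively,
W(t+1) = (I + eta F) W(t), so after any number of steps W = M W0 for some
(N_u, N_u) matrix M: every row of W stays inside the row space of the
initial matrix W0.  They therefore separate the already-compressed signals
W0 x but cannot *learn* a dimensionality reduction.  The ICA-mixture
algorithm updates the pseudo-inverse of each model's W the same way and
inherits the analogous column-space limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .priors import PriorModel

__all__ = [
    "IcaMixtureState",
    "natural_gradient_step",
    "nonholonomic_step",
    "ica_mixture_init",
    "ica_mixture_step",
    "responsibilities",
    "row_space_preserved",
]

_RANK_RTOL = 1e-8


def _check_batch(W: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    W = np.asarray(W, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != W.shape[1]:
        raise ValueError(f"W is {W.shape} but batch rows are {X.shape[0]}")
    if X.shape[1] == 0:
        raise ValueError("batch must be non-empty")
    return W, X


def natural_gradient_step(
    W: np.ndarray, X: np.ndarray, prior: PriorModel, eta: float
) -> np.ndarray:
    """W' = (I + eta F) W with F = I - <g(u) u^T> over the batch."""
    W, X = _check_batch(W, X)
    U = W @ X
    F = np.eye(W.shape[0]) - (prior.g(U) @ U.T) / X.shape[1]
    W_new = W + eta * F @ W
    if not np.all(np.isfinite(W_new)):
        raise FloatingPointError("natural-gradient update diverged")
    return W_new


def nonholonomic_step(
    W: np.ndarray, X: np.ndarray, prior: PriorModel, eta: float
) -> np.ndarray:
    """W' = (I + eta F) W with F = <diag[g(u) o u] - g(u) u^T>.

    The diagonal of F cancels exactly, which leaves the per-row scale of W
    free (the non-holonomic constraint).
    """
    W, X = _check_batch(W, X)
    U = W @ X
    G = prior.g(U)
    F = np.diag((G * U).mean(axis=1)) - (G @ U.T) / X.shape[1]
    W_new = W + eta * F @ W
    if not np.all(np.isfinite(W_new)):
        raise FloatingPointError("non-holonomic update diverged")
    return W_new


@dataclass
class IcaMixtureState:
    """One ICA model per context, parametrised by pseudo-inverses.

    ``pinv_W_list[k]`` is (W^k)^+ of shape (N_x, N_u); the unmixing matrix
    of model k is recovered as pinv((W^k)^+).
    """

    pinv_W_list: list[np.ndarray]

    @property
    def k_count(self) -> int:
        return len(self.pinv_W_list)

    def unmixing(self, k: int) -> np.ndarray:
        return np.linalg.pinv(self.pinv_W_list[k])


def ica_mixture_init(
    n_models: int, n_u: int, n_x: int, seed: int = 0, scale: float = 1.0
) -> IcaMixtureState:
    """Random initial mixture state with i.i.d. normal pseudo-inverses."""
    rng = np.random.default_rng(seed)
    return IcaMixtureState(
        pinv_W_list=[rng.normal(0.0, scale, size=(n_x, n_u)) for _ in range(n_models)]
    )


def responsibilities(
    x: np.ndarray, state: IcaMixtureState, prior: PriorModel
) -> np.ndarray:
    """Posterior probability z_k of each model having generated x.

    Uses the standard mixture likelihood z_k propto |det W^k| prod_i
    p0((W^k x)_i), a form adopted from the ICA-mixture literature (the
    update law alone does not fix it).  Requires square W (N_u = N_x).
    """
    x = np.asarray(x, dtype=float).ravel()
    logliks = np.empty(state.k_count)
    for k, pw in enumerate(state.pinv_W_list):
        Wk = np.linalg.pinv(pw)
        if Wk.shape[0] != Wk.shape[1]:
            raise ValueError("responsibilities require square unmixing matrices")
        sign, logdet = np.linalg.slogdet(Wk)
        if sign == 0:
            logliks[k] = -np.inf
            continue
        u = Wk @ x
        logliks[k] = logdet - prior.neg_log_density(u).sum()
    if np.all(np.isinf(logliks)):
        warnings.warn("all model likelihoods vanished; using uniform z", stacklevel=2)
        return np.full(state.k_count, 1.0 / state.k_count)
    z = np.exp(logliks - logliks.max())
    return z / z.sum()


def ica_mixture_step(
    state: IcaMixtureState,
    x: np.ndarray,
    prior: PriorModel,
    eta: float,
    z: np.ndarray | None = None,
) -> IcaMixtureState:
    """One online update of every model's pseudo-inverse.

    (W^k)^+ <- (W^k)^+ (I + eta z_k (I - g(u) u^T)) with u = W^k x.  The
    right-multiplicative form means the column space of each (W^k)^+ never
    grows.
    """
    x = np.asarray(x, dtype=float).ravel()
    if z is None:
        z = responsibilities(x, state, prior)
    z = np.asarray(z, dtype=float)
    if z.shape != (state.k_count,):
        raise ValueError("z must have one entry per model")
    new_list = []
    for k, pw in enumerate(state.pinv_W_list):
        if z[k] == 0.0:
            new_list.append(pw.copy())
            continue
        Wk = np.linalg.pinv(pw)
        u = Wk @ x
        n_u = u.size
        factor = np.eye(n_u) + eta * z[k] * (np.eye(n_u) - np.outer(prior.g(u), u))
        new = pw @ factor
        if not np.all(np.isfinite(new)):
            raise FloatingPointError(f"mixture model {k} update diverged")
        new_list.append(new)
    return IcaMixtureState(pinv_W_list=new_list)


def row_space_preserved(
    W: np.ndarray, W0: np.ndarray, tol: float = 1e-6
) -> bool:
    """True iff every row of W lies in the row space of W0 (within tol).

    Checked through numerical ranks: rank of the vertically stacked
    (W; W0) equals rank of W0 exactly when no row of W escapes.  ``tol``
    is the relative singular-value threshold.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    W0 = np.atleast_2d(np.asarray(W0, dtype=float))
    if W.shape[1] != W0.shape[1]:
        raise ValueError("W and W0 must have the same number of columns")

    def rank(m: np.ndarray) -> int:
        s = np.linalg.svd(m, compute_uv=False)
        return int(np.sum(s > tol * s[0])) if s.size and s[0] > 0 else 0

    return rank(np.vstack([W, W0])) == rank(W0)
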