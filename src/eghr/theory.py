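"""Existence and stability theory for multi-context separation solutions.

A synaptic matrix W solves the multi-context task when
W (A^(1), ..., A^(C)) = (Omega^(1), ..., Omega^(C)) with each Omega a
signed permutation; such a W exists iff the concatenated mixing block has
full column rank, which for generic matrices requires N_x >= C N_s and
N_u >= N_s.  For time-varying mixing A(t) = A^(0) + A^(1) R(t) the target
is W (A^(0), A^(1)) = (Omega, O), built here explicitly from the SVD of
the concatenated block.  Linear stability of a solution is governed by the
source/prior coefficients Phi: stable iff Phi_ii > -1 and
Phi_ij Phi_ji > 1 for all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .mixing import MixingModel
from .priors import PriorModel
from .sources import laplace_sampler

__all__ = [
    "StabilityCoefficients",
    "ExistenceResult",
    "multicontext_solution_exists",
    "capacity_conditions",
    "reference_solution",
    "phi_coefficients",
    "phi_extrapolated",
    "linear_stability",
    "fixed_point_residual",
]

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class StabilityCoefficients:
    """The Phi coefficients entering the second differential of the cost.

    phi_diag[i]       = cov[-log p0(s_i), g'(s_i) s_i^2]
    phi_offdiag[i, j] = cov[-log p0(s_i), g'(s_i)] <s_j^2>
                        + cov[-log p0(s_j), s_j^2] <g'(s_i)>   (i != j)

    The bare s_j^2 and g'(s_i) factors are taken as expectations (the
    covariances already consume the paired variables).  The diagonal of
    ``phi_offdiag`` is unused.
    """

    phi_diag: np.ndarray
    phi_offdiag: np.ndarray
    method: Literal["analytic", "monte_carlo"]
    n_samples: int | None = None


class ExistenceResult(NamedTuple):
    exists: bool
    rank: int
    required_rank: int


def _numerical_rank(m: np.ndarray) -> int:
    s = np.linalg.svd(m, compute_uv=False)
    if s.size == 0:
        return 0
    return int(np.sum(s > _RANK_RTOL * s[0]))


def multicontext_solution_exists(
    A_list: Sequence[np.ndarray],
) -> ExistenceResult:
    """Does a W with W A^(k) = Omega^(k) for all k exist?

    True iff the horizontally concatenated block (A^(1), ..., A^(C)) has
    full column rank C N_s.
    """
    if len(A_list) == 0:
        raise ValueError("need at least one mixing matrix")
    mats = [np.atleast_2d(np.asarray(a, dtype=float)) for a in A_list]
    n_x = mats[0].shape[0]
    if any(m.shape[0] != n_x for m in mats):
        raise ValueError("all mixing matrices must share the row dimension")
    block = np.hstack(mats)
    required = block.shape[1]
    rank = _numerical_rank(block)
    return ExistenceResult(exists=rank == required, rank=rank, required_rank=required)


def capacity_conditions(
    n_x: int, n_u: int, n_s: int, n_contexts: int
) -> tuple[bool, bool]:
    """(N_x >= C N_s, N_u >= N_s): necessary for a generic multi-context
    solution."""
    return n_x >= n_contexts * n_s, n_u >= n_s


def reference_solution(
    A0: np.ndarray,
    A1: np.ndarray | None = None,
    omega: np.ndarray | None = None,
) -> np.ndarray:
    """Construct W with W A^(0) = Omega and W A^(1) = O from an SVD.

    Writing the concatenated block (A^(0), A^(1)) = U S (V0^T, V1^T) with
    U column-orthonormal and V0 V1^T = O, the choice W = Omega V0 S^-1 U^T
    satisfies W (A^(0), A^(1)) = (Omega, O) exactly; it exists iff the
    block has full column rank.  ``omega`` defaults to the identity; with
    ``A1=None`` the construction reduces to W = Omega A0^+.
    Every call verifies the product post-condition to 1e-8.
    """
    A0 = np.atleast_2d(np.asarray(A0, dtype=float))
    n_x, n_s = A0.shape
    if omega is None:
        omega = np.eye(n_s)
    omega = np.asarray(omega, dtype=float)
    block = A0 if A1 is None else np.hstack([A0, np.atleast_2d(np.asarray(A1, float))])
    n_cols = block.shape[1]
    if _numerical_rank(block) < n_cols:
        res = multicontext_solution_exists([block])
        raise np.linalg.LinAlgError(
            f"no solution: concatenated block has rank {res.rank} < "
            f"{n_cols} (full column rank required)"
        )
    u, s, vt = np.linalg.svd(block, full_matrices=False)
    v0 = vt[:, :n_s].T  # (n_s, n_cols): first N_s rows of V
    W = omega @ v0 @ np.diag(1.0 / s) @ u.T
    # post-condition self-check
    if not np.allclose(W @ A0, omega, atol=1e-8):
        raise np.linalg.LinAlgError("reference solution failed W A0 = Omega check")
    if A1 is not None and not np.allclose(W @ np.atleast_2d(A1), 0.0, atol=1e-8):
        raise np.linalg.LinAlgError("reference solution failed W A1 = O check")
    return W


def _g_prime_samples(
    prior: PriorModel, s: np.ndarray, smoothing: float
) -> np.ndarray:
    """g'(s) samples; for non-smooth priors g is replaced by its tanh
    smoothing g_beta(u) = sqrt(2) tanh(u / beta), whose derivative is
    (sqrt(2)/beta) sech^2(u/beta)."""
    if not prior.smooth:
        if smoothing <= 0:
            raise ValueError(
                f"prior {prior.name!r} has a distributional g'; a positive "
                "smoothing width is required"
            )
        # sech^2(y) computed via exp(-|y|) to avoid cosh overflow
        e = np.exp(-np.abs(s / smoothing))
        return (np.sqrt(2.0) / smoothing) * (2.0 * e / (1.0 + e**2)) ** 2
    h = max(smoothing, 1e-6)
    return (prior.g(s + h) - prior.g(s - h)) / (2 * h)


_ANALYTIC_PHI = {
    # matched unit-variance source/prior pairs: (phi_ii, phi_ij)
    "laplace": (0.0, 2.0),
    "gaussian": (1.0, 1.0),
}


def phi_coefficients(
    prior: PriorModel,
    source_sampler=None,
    method: Literal["analytic", "monte_carlo"] = "monte_carlo",
    n_samples: int = 100_000,
    smoothing: float = 0.01,
    seed: int = 0,
    n_units: int = 2,
) -> StabilityCoefficients:
    """Estimate the stability coefficients Phi_ii and Phi_ij.

    ``analytic`` returns closed-form values for the matched unit-variance
    Laplace and Gaussian source/prior pairs (the beta -> 0 limit of the
    smoothed estimator).  ``monte_carlo`` estimates all covariances and
    means from ``source_sampler(n, rng)`` draws, with ``smoothing`` the
    tanh width beta used where g' is distributional.
    """
    if method == "analytic":
        if prior.name not in _ANALYTIC_PHI:
            raise ValueError(f"no analytic Phi for prior {prior.name!r}")
        d, o = _ANALYTIC_PHI[prior.name]
        off = np.full((n_units, n_units), o)
        np.fill_diagonal(off, 0.0)
        return StabilityCoefficients(
            phi_diag=np.full(n_units, d), phi_offdiag=off, method="analytic"
        )
    if source_sampler is None:
        source_sampler = laplace_sampler(n_units)
    rng = np.random.default_rng(seed)
    s = np.asarray(source_sampler(n_samples, rng), dtype=float)
    n_units = s.shape[0]
    nld = prior.neg_log_density(s)
    gp = _g_prime_samples(prior, s, smoothing)
    s2 = s**2

    def cov_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return ((a - a.mean(1, keepdims=True)) * (b - b.mean(1, keepdims=True))).mean(1)

    phi_diag = cov_rows(nld, gp * s2)
    c_nld_gp = cov_rows(nld, gp)  # per unit i
    c_nld_s2 = cov_rows(nld, s2)  # per unit j
    m_s2 = s2.mean(axis=1)
    m_gp = gp.mean(axis=1)
    off = c_nld_gp[:, None] * m_s2[None, :] + c_nld_s2[None, :] * m_gp[:, None]
    np.fill_diagonal(off, 0.0)
    return StabilityCoefficients(
        phi_diag=phi_diag, phi_offdiag=off, method="monte_carlo",
        n_samples=n_samples,
    )


def phi_extrapolated(
    prior: PriorModel,
    source_sampler=None,
    betas: Sequence[float] = (0.1, 0.03, 0.01),
    n_samples: int = 200_000,
    seed: int = 0,
    n_units: int = 2,
) -> tuple[float, float]:
    """Mean (Phi_ii, Phi_ij) extrapolated to the beta -> 0 limit.

    Fits a straight line in beta through Monte-Carlo estimates at the
    given smoothing widths and returns the intercepts — a Richardson-style
    treatment of the distributional derivative in g'.
    """
    betas = np.asarray(betas, dtype=float)
    d_vals, o_vals = [], []
    for i, b in enumerate(betas):
        phi = phi_coefficients(
            prior, source_sampler, method="monte_carlo", n_samples=n_samples,
            smoothing=float(b), seed=seed + i, n_units=n_units,
        )
        d_vals.append(phi.phi_diag.mean())
        mask = ~np.eye(phi.phi_offdiag.shape[0], dtype=bool)
        o_vals.append(phi.phi_offdiag[mask].mean())
    coef_d = np.polyfit(betas, d_vals, 1)
    coef_o = np.polyfit(betas, o_vals, 1)
    return float(coef_d[-1]), float(coef_o[-1])


def linear_stability(
    phi: StabilityCoefficients,
) -> tuple[bool, list[tuple[int, ...]]]:
    """Stability verdict: stable iff Phi_ii > -1 for all i and
    Phi_ij Phi_ji > 1 for all i != j.  Returns the verdict and the list of
    violating indices — ``(i,)`` for a diagonal violation, ``(i, j)`` for
    a pair."""
    violations: list[tuple[int, ...]] = []
    for i, d in enumerate(phi.phi_diag):
        if not d > -1.0:
            violations.append((i,))
    off = phi.phi_offdiag
    n = off.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if not off[i, j] * off[j, i] > 1.0:
                violations.append((i, j))
    return len(violations) == 0, violations


def fixed_point_residual(
    W: np.ndarray,
    mixing: "MixingModel | np.ndarray",
    prior: PriorModel,
    E0: float,
    n_samples: int = 10_000,
    seed: int = 0,
    source_sampler=None,
) -> float:
    """Monte-Carlo norm of the expected update at W.

    Estimates |<(E0 - E(u)) g(u) x^T>|_F over fresh sources; for a true
    solution this is a pure sampling fluctuation decaying as
    O(1/sqrt(n_samples)), while a non-solution has a bias that does not
    vanish.  For per-context mixing the residual norms are averaged over
    contexts.
    """
    from .rule import global_factor, outputs  # local import avoids a cycle

    if isinstance(mixing, np.ndarray):
        mats = [mixing]
    elif mixing.kind == "time_varying":
        mats = [mixing.matrices[0]]
    else:
        mats = list(mixing.matrices)
    n_s = mats[0].shape[1]
    if source_sampler is None:
        source_sampler = laplace_sampler(n_s)
    rng = np.random.default_rng(seed)
    norms = []
    for a in mats:
        s = source_sampler(n_samples, rng)
        x = a @ s
        u = outputs(W, x)
        gate = E0 - global_factor(u, prior)
        grad = (prior.g(u) * gate) @ x.T / n_samples
        norms.append(np.linalg.norm(grad))
    return float(np.mean(norms))
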