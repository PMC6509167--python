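"""Evaluation quantities: transform matrix K, BSS error, Frobenius overlap,
signed-permutation matching, and PCA projection of training trajectories.

Separation succeeds when K = W A is the identity up to permutations and
sign-flips, i.e. exactly one dominant entry per row and per column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BssErrorReport",
    "transform_matrix",
    "bss_error",
    "frobenius_overlap",
    "match_permutation_signs",
    "pca_projection",
]


@dataclass(frozen=True)
class BssErrorReport:
    """Per-column/per-row confusion ratios and their normalised total.

    For column j, ``per_column_ratios[j]`` is |second-largest| / |largest|
    over that column's entries (0 = one output wholly owns the source,
    1 = two outputs respond equally); row ratios analogously.  The total is
    sum(col ratios)/(2 N_s) + sum(row ratios)/(2 N_u), which lies in [0, 1]
    and is 0 iff the mapping is one-to-one.
    """

    per_column_ratios: np.ndarray
    per_row_ratios: np.ndarray
    total: float


def transform_matrix(W: np.ndarray, A: np.ndarray) -> np.ndarray:
    """K = W A, the net source-to-output map (equals Cov(u, s) for
    unit-variance independent sources)."""
    W = np.asarray(W)
    A = np.asarray(A)
    if W.shape[1] != A.shape[0]:
        raise ValueError(
            f"inner dimensions do not match: W is {W.shape}, A is {A.shape}"
        )
    return W @ A


def _second_to_first_ratios(K_abs: np.ndarray) -> np.ndarray:
    """Ratio of second-largest to largest entry down each column of K_abs.

    Argmax ties break to the lowest index.  An all-zero column scores 1
    (maximal confusion): the formula is otherwise undefined and a dead
    column should not read as perfect separation.
    """
    n_rows, n_cols = K_abs.shape
    ratios = np.empty(n_cols)
    for j in range(n_cols):
        col = K_abs[:, j]
        i1 = int(np.argmax(col))
        if col[i1] == 0.0:
            ratios[j] = 1.0
            continue
        rest = np.delete(col, i1)
        ratios[j] = rest.max() / col[i1] if rest.size else 0.0
    return ratios


def bss_error(K: np.ndarray) -> BssErrorReport:
    """The separation-error metric on the transform matrix K.

    Zero iff each row and each column of K has exactly one nonzero entry
    (one-to-one source/output mapping, up to permutation and sign); at most
    one.  Invariant under row/column permutations, sign flips, and global
    rescaling of K.  A 1x1 K has no competitor, so its error is 0.
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    K_abs = np.abs(K)
    col = _second_to_first_ratios(K_abs)
    row = _second_to_first_ratios(K_abs.T)
    n_u, n_s = K.shape
    total = float(col.sum() / (2 * n_s) + row.sum() / (2 * n_u))
    return BssErrorReport(per_column_ratios=col, per_row_ratios=row, total=total)


def frobenius_overlap(W: np.ndarray, A: np.ndarray) -> float:
    """|W A|_F — the overlap between a synaptic matrix and a mixing
    component.  Zero iff every row of W is orthogonal to every column
    of A."""
    return float(np.linalg.norm(transform_matrix(W, A)))


def match_permutation_signs(
    K: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy signed-permutation matching of outputs to sources.

    Repeatedly assigns the globally largest remaining |K_ij|, pairing
    output i with source j and taking the entry's sign.  Returns
    ``(perm, signs, residual)`` where ``perm[j]`` is the output assigned to
    source j, ``signs[j]`` its sign, and ``residual`` is
    |K - P diag(signs)|_F for square K (the distance from an exact signed
    permutation), else NaN.
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    n_u, n_s = K.shape
    if n_u < n_s:
        raise ValueError("need at least as many outputs as sources to match")
    work = np.abs(K).copy()
    perm = np.full(n_s, -1, dtype=int)
    signs = np.ones(n_s)
    for _ in range(n_s):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        perm[j] = i
        signs[j] = 1.0 if K[i, j] >= 0 else -1.0
        work[i, :] = -1.0
        work[:, j] = -1.0
    if n_u == n_s:
        target = np.zeros_like(K)
        target[perm, np.arange(n_s)] = signs
        residual = float(np.linalg.norm(K - target))
    else:
        residual = float("nan")
    return perm, signs, residual


def pca_projection(
    snapshots: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Project a trajectory of matrices onto its leading principal components.

    Each snapshot is flattened; the trajectory is centred across snapshots
    and decomposed by SVD.  Returns ``(coords, variance_fractions)`` with
    ``coords`` of shape (n_snapshots, n_components) and per-component
    explained-variance fractions (summing to <= 1).
    """
    snaps = np.asarray(snapshots, dtype=float)
    if snaps.ndim < 2 or snaps.shape[0] < 2:
        raise ValueError("need at least two snapshots for a PCA projection")
    flat = snaps.reshape(snaps.shape[0], -1)
    if not 1 <= n_components <= flat.shape[0] - 1:
        raise ValueError("need 1 <= n_components <= n_snapshots - 1")
    centred = flat - flat.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    coords = centred @ vt[:n_components].T
    var = s**2
    fractions = var[:n_components] / var.sum() if var.sum() > 0 else var[:n_components]
    return coords, fractions
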