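"""Per-unit prior models for the learning rule.

The agent assumes its outputs follow a factorised prior p0(u) = prod p0(u_i).
A :class:`PriorModel` bundles the per-unit negative log-density E(u_i), its
derivative g = dE/du (the nonlinearity of the rule), and the analytic
per-unit entropy needed to calibrate the output scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["PriorModel", "laplace_prior", "gaussian_prior"]

_HALF_LN2 = 0.5 * np.log(2.0)


@dataclass(frozen=True)
class PriorModel:
    """A per-unit prior: -log p0, its derivative g, and analytic moments.

    Attributes
    ----------
    neg_log_density : callable
        Elementwise u -> -log p0(u).
    g : callable
        Elementwise derivative of ``neg_log_density`` (the score-like
        nonlinearity of the learning rule).
    per_unit_entropy : float or None
        <-log p0(s)> under the matched source distribution, if known in
        closed form; used by the E0 calibration.
    name : str
    smooth : bool
        Whether g is differentiable everywhere (needed where g' appears in
        stability formulas without smoothing).
    """

    neg_log_density: Callable[[np.ndarray], np.ndarray]
    g: Callable[[np.ndarray], np.ndarray]
    per_unit_entropy: float | None
    name: str
    smooth: bool = True


def laplace_prior() -> PriorModel:
    """Unit-variance Laplace prior: -log p0(u) = sqrt(2)|u| + (1/2) ln 2.

    g(u) = sqrt(2) sign(u), with the subgradient 0 at u = 0 (a measure-zero
    event; keeps the update odd-symmetric).  The matched-source entropy is
    1 + (1/2) ln 2 per unit.
    """
    sqrt2 = np.sqrt(2.0)

    def nld(u: np.ndarray) -> np.ndarray:
        return sqrt2 * np.abs(u) + _HALF_LN2

    def g(u: np.ndarray) -> np.ndarray:
        return sqrt2 * np.sign(u)

    return PriorModel(
        neg_log_density=nld,
        g=g,
        per_unit_entropy=1.0 + _HALF_LN2,
        name="laplace",
        smooth=False,
    )


def gaussian_prior() -> PriorModel:
    """Standard normal prior: -log p0(u) = u^2/2 + (1/2) ln 2 pi, g(u) = u.

    Included as the degenerate reference case: a Gaussian prior cannot
    break rotational symmetry, so it does not separate sources.
    """
    half_ln_2pi = 0.5 * np.log(2.0 * np.pi)

    def nld(u: np.ndarray) -> np.ndarray:
        return 0.5 * np.square(u) + half_ln_2pi

    def g(u: np.ndarray) -> np.ndarray:
        return np.asarray(u, dtype=float)

    return PriorModel(
        neg_log_density=nld,
        g=g,
        per_unit_entropy=0.5 + half_ln_2pi,
        name="gaussian",
        smooth=True,
    )
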