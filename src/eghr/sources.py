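"""Hidden-source generators.

Sources follow the rows-are-sources, columns-are-time-steps convention used
throughout the package: a batch of ``T`` samples of ``N_s`` sources is an
``(N_s, T)`` float array.  All generators normalise (or are parametrised) to
zero mean and unit variance per source, the scale the learning rule's
``E0`` calibration assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SourceBatch",
    "sample_laplace_sources",
    "laplace_sampler",
    "make_songlike_sources",
    "songlike_sampler",
]

# unit-variance Laplace density p(s) = (1/sqrt(2)) exp(-sqrt(2)|s|)
_LAPLACE_SCALE = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class SourceBatch:
    """A matrix of hidden source values, one row per source.

    Attributes
    ----------
    values : ndarray of shape (n_sources, n_steps)
        Dimensionless source amplitudes.
    seed : int
        Seed used to generate the batch (for provenance).
    """

    values: np.ndarray
    seed: int = field(default=0)

    @property
    def n_sources(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


def _check_dims(n_sources: int, n_steps: int) -> None:
    if n_sources < 1 or n_steps < 1:
        raise ValueError(
            f"source batch dimensions must be positive, got "
            f"({n_sources}, {n_steps})"
        )


def sample_laplace_sources(n_sources: int, n_steps: int, seed: int) -> SourceBatch:
    """Draw i.i.d. sources from the zero-mean, unit-variance Laplace density.

    The density is p(s) = (1/sqrt(2)) exp(-sqrt(2)|s|), i.e. a Laplace
    distribution with scale b = 1/sqrt(2) so that Var(s) = 2 b^2 = 1.
    """
    _check_dims(n_sources, n_steps)
    rng = np.random.default_rng(seed)
    values = rng.laplace(0.0, _LAPLACE_SCALE, size=(n_sources, n_steps))
    return SourceBatch(values=values, seed=seed)


def laplace_sampler(n_sources: int):
    """Return a stateless sampler ``f(n, rng) -> (n_sources, n)`` of unit
    Laplace sources, for use by the training loop."""
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")

    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.laplace(0.0, _LAPLACE_SCALE, size=(n_sources, n))

    return sample


def _songlike_waveform(
    n_steps: int, sample_rate: float, fundamental: float, rng: np.random.Generator
) -> np.ndarray:
    """One deterministic-ish song-like waveform: an amplitude-modulated
    multi-harmonic chirp with syllable-like gaps.

    Emulates the gross structure of a birdsong recording (harmonic stacks,
    slow frequency sweeps, bursts separated by silences) without any audio
    input.  Randomness enters only through ``rng`` (syllable phases/rates).
    """
    t = np.arange(n_steps) / sample_rate
    # slow chirp of the fundamental +/- 20 %
    sweep_rate = rng.uniform(0.1, 0.4)
    inst_freq = fundamental * (1.0 + 0.2 * np.sin(2 * np.pi * sweep_rate * t))
    phase = 2 * np.pi * np.cumsum(inst_freq) / sample_rate
    wave = np.zeros(n_steps)
    for h, amp in ((1, 1.0), (2, 0.5), (3, 0.25)):
        wave += amp * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    # syllable envelope: rectified slow oscillation -> bursts and gaps
    syllable_rate = rng.uniform(2.0, 6.0)
    envelope = np.clip(np.sin(2 * np.pi * syllable_rate * t + rng.uniform(0, 2 * np.pi)), 0.0, None)
    return wave * envelope


def make_songlike_sources(
    n_sources: int,
    n_steps: int,
    sample_rate: float = 4410.0,
    seed: int = 0,
    noise_scale: float = 0.0,
) -> SourceBatch:
    """Generate synthetic song-like sources (a stand-in for recorded audio).

    Each source is an amplitude-modulated multi-harmonic chirp with a
    distinct fundamental frequency, optionally summed with white Laplace
    noise, then normalised row-wise to zero mean and unit variance.  Distinct
    chirps are close to uncorrelated, which is what the separation task
    requires of its sources.

    Parameters
    ----------
    sample_rate : float
        Nominal sampling rate in Hz; only sets the time axis of the chirps.
    noise_scale : float
        Standard deviation of additive white Laplace noise before the final
        normalisation (0 disables it).
    """
    _check_dims(n_sources, n_steps)
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    rng = np.random.default_rng(seed)
    values = np.empty((n_sources, n_steps))
    # distinct, non-harmonically-related fundamentals per source
    fundamentals = 400.0 * (1.37 ** np.arange(n_sources)) + rng.uniform(
        0, 50, size=n_sources
    )
    for i in range(n_sources):
        values[i] = _songlike_waveform(n_steps, sample_rate, fundamentals[i], rng)
    if noise_scale > 0:
        values += rng.laplace(0.0, noise_scale / np.sqrt(2.0), size=values.shape)
    values -= values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    values /= sd
    return SourceBatch(values=values, seed=seed)


def songlike_sampler(
    n_sources: int,
    total_steps: int,
    sample_rate: float = 4410.0,
    seed: int = 0,
    noise_scale: float = 0.1,
):
    """Sequential sampler over a pre-generated song-like waveform.

    Unlike :func:`laplace_sampler`, song-like sources are temporally
    structured, so the sampler walks through a fixed waveform in order,
    wrapping around at the end (the song repeats during training).
    """
    batch = make_songlike_sources(
        n_sources, total_steps, sample_rate=sample_rate, seed=seed,
        noise_scale=noise_scale,
    )
    pos = 0

    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        nonlocal pos
        idx = (pos + np.arange(n)) % total_steps
        pos = (pos + n) % total_steps
        return batch.values[:, idx]

    return sample
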