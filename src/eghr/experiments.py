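"""Config-driven reproductions of the five experiment protocols.

Each named experiment wires a source generator, a mixing regime, and the
trainer together, at native or scaled size, and reports the final
separation quality.  The native dimensions, learning rates and session
structures are the protocols' published values; batch sizes and scaled
run lengths are this package's own defaults, chosen so the scaled runs
converge on one CPU in minutes (see docs/methods.md).

Learning rates are quoted *online* (per consumed sample); the trainer
applies eta = batch_size * eta_online to the minibatch mean, which matches
the online rule over the same number of samples.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import bss_error, frobenius_overlap, transform_matrix
from .mixing import (
    ContextSchedule,
    MixingModel,
    context_vector_mixing,
    make_context_schedule,
    markov_switching_omega,
    ou_matrix_process,
    sample_mixing_matrix,
    time_varying_mixing,
    zero_sum_context_components,
)
from .priors import laplace_prior
from .rule import (
    NetworkState,
    TrainConfig,
    TrainTrajectory,
    init_network,
    train_eghr,
)
from .sources import laplace_sampler, songlike_sampler
from .theory import capacity_conditions

__all__ = [
    "EXPERIMENT_NAMES",
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "make_fixture",
    "FIXTURE_NAMES",
    "simplex_vectors",
    "training_context_vectors",
]

EXPERIMENT_NAMES = (
    "two_context",
    "hundred_context",
    "rotating",
    "songlike_moving",
    "context_vector_generalization",
)

# Native protocol parameters: eta_online values, dimensions, session
# structure and omega values as published; batch_size and the
# batch-step counts (sessions x steps_per_session x batch_size = consumed
# samples) are package defaults.
_DEFAULTS: dict[str, dict] = {
    "two_context": dict(
        n_s=2, n_x=6, n_u=2, n_contexts=2, eta_online=4e-6, batch_size=100,
        n_sessions=100, steps_per_session=1000, record_every=100,
        schedule_mode="alternating", mix_scale=1.0, init_scale=0.1,
    ),
    "hundred_context": dict(
        n_s=10, n_x=2000, n_u=10, n_contexts=100, eta_online=1e-5,
        batch_size=100, n_sessions=600, steps_per_session=1000,
        record_every=250, schedule_mode="uniform_random", mix_scale=1.0,
        init_scale=0.1,
    ),
    "rotating": dict(
        n_s=2, n_x=6, n_u=2, eta_online=1e-5, batch_size=50,
        n_steps=200_000, record_every=5000,
        omega=np.sqrt(2.0) * np.pi / 100.0, sample_rate=4410.0,
        dynamics="rotation", ou_tau=1e-3, ou_dt=1e-6, mix_scale=1.0,
        init_scale=0.1, anneal_steps=200_000, anneal_factor=5.0,
    ),
    "songlike_moving": dict(
        n_s=2, n_x=6, n_u=2, eta_online=1e-7, batch_size=50,
        n_steps=529_200, record_every=10_000, sample_rate=4410.0,
        p_switch=1.0 / 8820.0, noise_scale=0.3, mix_scale=1.0,
        init_scale=0.1, song_period=264_600,
    ),
    "context_vector_generalization": dict(
        n_s=10, n_x=100, n_u=10, n_components=4, eta_online=2e-7,
        batch_size=100, n_sessions=120, steps_per_session=26_460,
        record_every=1000, n_test_vectors=20, sources="songlike",
        sample_rate=4410.0, noise_scale=0.3, mix_scale=1.0, init_scale=0.1,
        song_period=264_600,
    ),
}

_SCALABLE_DIMS = ("n_x", "n_contexts")
_SCALABLE_STEPS = ("n_sessions", "steps_per_session", "n_steps")


@dataclass(frozen=True)
class ExperimentConfig:
    """A named experiment plus scaling, seeding and overrides.

    ``scale`` multiplies input dimension, context count and run length
    (floored to feasible minima); ``overrides`` replaces any protocol
    parameter outright after scaling.  ``applied()`` returns the final
    parameter set, recording native defaults alongside applied values.
    """

    name: str
    scale: float = 1.0
    seed: int = 0
    eta: float | None = None  # online rate override
    outdir: str | None = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from {EXPERIMENT_NAMES}"
            )
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        unknown = set(self.overrides) - set(_DEFAULTS[self.name])
        if unknown:
            raise ValueError(
                f"unknown override keys for {self.name}: {sorted(unknown)}"
            )

    def applied(self) -> dict:
        p = dict(_DEFAULTS[self.name])
        if self.scale != 1.0:
            for k in _SCALABLE_DIMS:
                if k in p:
                    p[k] = max(1, round(p[k] * self.scale))
            for k in _SCALABLE_STEPS:
                if k in p:
                    p[k] = max(1, round(p[k] * self.scale))
        p.update(self.overrides)
        if self.eta is not None:
            p["eta_online"] = self.eta
        return p


@dataclass
class ExperimentReport:
    """Final metrics of a run, recomputable from the stored trajectory."""

    name: str
    seed: int
    params: dict
    final_bss_per_context: list[float]
    final_overlaps: dict[str, float]
    final_cost: float
    test_bss_mean: float | None = None
    test_bss_per_vector: list[float] | None = None
    n_batch_steps: int = 0
    wall_clock_s: float = 0.0
    trajectory_path: str | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if not k.startswith("_")}
        d["params"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.params.items()}
        return d


def _eta_batch(p: dict) -> float:
    return p["eta_online"] * p["batch_size"]


def _check_capacity(p: dict, n_contexts: int) -> None:
    cap_x, cap_u = capacity_conditions(p["n_x"], p["n_u"], p["n_s"], n_contexts)
    if not (cap_x and cap_u):
        raise ValueError(
            f"infeasible dimensions: multi-context solutions require "
            f"N_x >= C N_s and N_u >= N_s, got N_x={p['n_x']}, "
            f"C={n_contexts}, N_s={p['n_s']}, N_u={p['n_u']}"
        )


def simplex_vectors(n: int, count: int, seed: int) -> np.ndarray:
    """``count`` vectors with entries in [0, 1] normalised to sum to 1."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.0, 1.0, size=(count, n))
    return v / v.sum(axis=1, keepdims=True)


def training_context_vectors(n_components: int) -> np.ndarray:
    """The fixed training set of context vectors.

    For four components this is the canonical ten-vector set (unit vectors
    plus half-half blends of component pairs); for two components, ten
    evenly spaced points on the 1-simplex; otherwise ten deterministic
    simplex samples.
    """
    if n_components == 4:
        return np.array(
            [
                (1, 0, 0, 0), (0.5, 0.5, 0, 0), (0, 1, 0, 0), (0, 0.5, 0.5, 0),
                (0, 0, 1, 0), (0, 0, 0.5, 0.5), (0, 0, 0, 1), (0.5, 0, 0, 0.5),
                (0.5, 0, 0.5, 0), (0, 0.5, 0, 0.5),
            ],
            dtype=float,
        )
    if n_components == 2:
        a = np.linspace(0.0, 1.0, 10)
        return np.column_stack([a, 1.0 - a])
    return simplex_vectors(n_components, 10, seed=12345)


def _sources_for(p: dict, total_samples: int, seed: int):
    if p.get("sources", "laplace") == "songlike":
        return songlike_sampler(
            p["n_s"], min(p["song_period"], max(total_samples, 1)),
            sample_rate=p["sample_rate"], seed=seed,
            noise_scale=p["noise_scale"],
        )
    return laplace_sampler(p["n_s"])


def _run_static_contexts(cfg: ExperimentConfig, p: dict):
    n_contexts = p["n_contexts"]
    _check_capacity(p, n_contexts)
    mats = tuple(
        sample_mixing_matrix(p["n_x"], p["n_s"], seed=cfg.seed * 1000 + k,
                             scale=p["mix_scale"])
        for k in range(n_contexts)
    )
    mixing = MixingModel(kind="per_context", matrices=mats)
    schedule = make_context_schedule(
        n_contexts, p["n_sessions"], p["steps_per_session"],
        mode=p["schedule_mode"], seed=cfg.seed + 7,
    )
    n_steps = p["n_sessions"] * p["steps_per_session"]
    sampler = _sources_for(p, n_steps * p["batch_size"], cfg.seed + 11)
    net = init_network(p["n_u"], p["n_x"], seed=cfg.seed + 1,
                       scale=p["init_scale"])
    tc = TrainConfig(
        eta=_eta_batch(p), batch_size=p["batch_size"], n_steps=n_steps,
        record_every=p["record_every"],
    )
    final, traj = train_eghr(net, sampler, mixing, schedule, laplace_prior(), tc)
    return final, traj, mixing


def _rotation_stack(angles: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles), np.sin(angles)
    return np.stack(
        [np.stack([c, -s], axis=-1), np.stack([s, c], axis=-1)], axis=-2
    )


def _run_time_varying(cfg: ExperimentConfig, p: dict, songlike: bool):
    a0 = sample_mixing_matrix(p["n_x"], p["n_s"], seed=cfg.seed * 1000,
                              scale=p["mix_scale"])
    a1 = sample_mixing_matrix(p["n_x"], 2, seed=cfg.seed * 1000 + 1,
                              scale=p["mix_scale"])
    # R is generated at batch-step resolution (held within each batch):
    # angular frequencies are in rad/s and one sample advances time by
    # 1/sample_rate s, so one batch advances batch_size/sample_rate s —
    # small enough that R barely moves inside a batch.
    # optional second, slower phase: the first phase selects the basin of
    # the time-invariant solution, the second lowers the stochastic noise
    # floor around it
    anneal_steps = int(p.get("anneal_steps", 0))
    n_steps = p["n_steps"] + anneal_steps
    dt_batch = p["batch_size"] / p["sample_rate"]
    if songlike:
        # per-batch redraw probability from the per-sample one
        p_batch = 1.0 - (1.0 - p["p_switch"]) ** p["batch_size"]
        omega_seq = markov_switching_omega(
            n_steps, p_switch=p_batch, seed=cfg.seed + 3
        )
        angles = np.cumsum(omega_seq) * dt_batch
        r_traj = _rotation_stack(angles)
        sampler = _sources_for(
            {**p, "sources": "songlike"}, n_steps * p["batch_size"], cfg.seed + 11
        )
    elif p["dynamics"] == "rotation":
        angles = p["omega"] * dt_batch * np.arange(n_steps)
        r_traj = _rotation_stack(angles)
        sampler = laplace_sampler(p["n_s"])
    elif p["dynamics"] == "ou":
        # tau is quoted per sample-time unit of 1e-3 s: with dt_ou = ou_dt
        # per sample, one batch advances batch_size * ou_dt
        r_traj = ou_matrix_process(
            2, p["n_s"], p["ou_tau"], n_steps,
            min(p["ou_dt"] * p["batch_size"], 0.5 * p["ou_tau"]),
            seed=cfg.seed + 3,
        )
        sampler = laplace_sampler(p["n_s"])
    else:
        raise ValueError(f"unknown dynamics {p['dynamics']!r}")
    net = init_network(p["n_u"], p["n_x"], seed=cfg.seed + 1,
                       scale=p["init_scale"])
    mixing = time_varying_mixing(a0, a1, r_traj[: p["n_steps"]])
    tc = TrainConfig(
        eta=_eta_batch(p), batch_size=p["batch_size"], n_steps=p["n_steps"],
        record_every=p["record_every"],
    )
    final, traj = train_eghr(net, sampler, mixing, None, laplace_prior(), tc)
    if anneal_steps > 0:
        mixing2 = time_varying_mixing(a0, a1, r_traj[p["n_steps"] :])
        tc2 = TrainConfig(
            eta=_eta_batch(p) / p.get("anneal_factor", 5.0),
            batch_size=p["batch_size"], n_steps=anneal_steps,
            record_every=p["record_every"],
        )
        final2 = NetworkState(W=final.W, step=final.step,
                              rng_seed=cfg.seed + 17)
        final, traj2 = train_eghr(net=final2, source_sampler=sampler,
                                  mixing=mixing2, schedule=None,
                                  prior=laplace_prior(), cfg=tc2)
        traj = TrainTrajectory(
            times=np.concatenate([traj.times, traj2.times[1:] + p["n_steps"]]),
            cost=np.concatenate([traj.cost, traj2.cost[1:]]),
            bss_error_per_context=np.vstack(
                [traj.bss_error_per_context, traj2.bss_error_per_context[1:]]
            ),
            overlaps=np.vstack([traj.overlaps, traj2.overlaps[1:]]),
            overlap_names=traj.overlap_names,
            W_snapshots=np.vstack([traj.W_snapshots, traj2.W_snapshots[1:]]),
        )
    return final, traj, time_varying_mixing(a0, a1, r_traj)


def _run_context_vectors(cfg: ExperimentConfig, p: dict):
    comps = zero_sum_context_components(
        p["n_x"], p["n_s"], seed=cfg.seed * 1000, n_components=p["n_components"],
        scale=p["mix_scale"],
    )
    a0, deps = comps[0], list(comps[1:])
    train_vs = training_context_vectors(p["n_components"])
    mats = tuple(context_vector_mixing(a0, deps, v) for v in train_vs)
    # W(A0, A1, ..., An) = (Omega, O, ..., O) needs the block to have full
    # column rank; the zero-sum components span (n-1) N_s dimensions, so
    # N_x >= n N_s suffices generically.
    if p["n_x"] < p["n_components"] * p["n_s"]:
        raise ValueError(
            "infeasible dimensions for context-vector mixing: need "
            f"N_x >= n_components * N_s = "
            f"{p['n_components'] * p['n_s']}, got N_x={p['n_x']}"
        )
    mixing = MixingModel(kind="per_context", matrices=mats)
    schedule = make_context_schedule(
        len(mats), p["n_sessions"], p["steps_per_session"],
        mode="uniform_random", seed=cfg.seed + 7,
    )
    n_steps = p["n_sessions"] * p["steps_per_session"]
    sampler = _sources_for(p, n_steps * p["batch_size"], cfg.seed + 11)
    net = init_network(p["n_u"], p["n_x"], seed=cfg.seed + 1,
                       scale=p["init_scale"])
    tc = TrainConfig(
        eta=_eta_batch(p), batch_size=p["batch_size"], n_steps=n_steps,
        record_every=p["record_every"],
    )
    final, traj = train_eghr(net, sampler, mixing, schedule, laplace_prior(), tc)
    test_vs = simplex_vectors(p["n_components"], p["n_test_vectors"],
                              seed=cfg.seed + 99)
    test_mats = [context_vector_mixing(a0, deps, v) for v in test_vs]
    test_bss = [bss_error(transform_matrix(final.W, a)).total for a in test_mats]
    overlaps = {"A0": frobenius_overlap(final.W, a0)}
    overlaps.update(
        {f"A{k + 1}": frobenius_overlap(final.W, d) for k, d in enumerate(deps)}
    )
    return final, traj, mixing, test_bss, overlaps


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Run a named experiment end to end; deterministic given seed."""
    t0 = time.perf_counter()
    p = cfg.applied()
    test_bss = None
    extra_overlaps = None
    if cfg.name in ("two_context", "hundred_context"):
        final, traj, mixing = _run_static_contexts(cfg, p)
    elif cfg.name == "rotating":
        final, traj, mixing = _run_time_varying(cfg, p, songlike=False)
    elif cfg.name == "songlike_moving":
        final, traj, mixing = _run_time_varying(cfg, p, songlike=True)
    else:
        final, traj, mixing, test_bss, extra_overlaps = _run_context_vectors(cfg, p)

    final_bss = list(traj.bss_error_per_context[-1])
    overlaps = extra_overlaps or dict(
        zip(traj.overlap_names, traj.overlaps[-1].tolist())
    )
    report = ExperimentReport(
        name=cfg.name,
        seed=cfg.seed,
        params={k: v for k, v in p.items()},
        final_bss_per_context=[float(b) for b in final_bss],
        final_overlaps={k: float(v) for k, v in overlaps.items()},
        final_cost=float(traj.cost[-1]),
        test_bss_mean=float(np.mean(test_bss)) if test_bss is not None else None,
        test_bss_per_vector=[float(b) for b in test_bss] if test_bss else None,
        n_batch_steps=int(traj.times[-1]),
        wall_clock_s=time.perf_counter() - t0,
    )
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        tpath = out / f"{cfg.name}_trajectory.csv"
        write_trajectory(traj, tpath)
        report.trajectory_path = str(tpath)
        (out / f"{cfg.name}_report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        # self-consistency: report numbers must match the stored trajectory
        back = read_trajectory(tpath)
        if not np.allclose(back.bss_error_per_context[-1], final_bss):
            raise RuntimeError("stored trajectory disagrees with report")
    report._trajectory = traj  # in-memory attachment for callers
    return report


_CONFIG_KEYS = {"name", "scale", "seed", "eta", "outdir", "overrides"}


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML file.

    Top-level keys: ``name`` (required), ``scale``, ``seed``, ``eta``,
    ``outdir`` and an ``overrides`` mapping of protocol parameters.
    Unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "name" not in raw:
        raise ValueError("config must set 'name'")
    return ExperimentConfig(**raw)


def write_trajectory(traj: TrainTrajectory, path: str | Path) -> Path:
    """Write a trajectory as a CSV table plus an .npz sidecar of W snapshots.

    Columns: step, cost, one bss_* column per tracked context, one
    overlap_* column per tracked component.  Floats are written with 17
    significant digits so the paired reader round-trips losslessly.
    """
    if len(traj) == 0:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    cols: dict[str, np.ndarray] = {"step": traj.times, "cost": traj.cost}
    for c in range(traj.bss_error_per_context.shape[1]):
        cols[f"bss_c{c + 1}"] = traj.bss_error_per_context[:, c]
    for i, name in enumerate(traj.overlap_names):
        cols[f"overlap_{name}"] = traj.overlaps[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    np.savez_compressed(
        path.with_suffix(".snapshots.npz"),
        W_snapshots=traj.W_snapshots,
        overlap_names=np.array(traj.overlap_names, dtype=object),
    )
    return path


def read_trajectory(path: str | Path) -> TrainTrajectory:
    """Inverse of :func:`write_trajectory`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    bss_cols = [c for c in df.columns if c.startswith("bss_c")]
    ov_cols = [c for c in df.columns if c.startswith("overlap_")]
    snaps = np.empty((0, 0, 0))
    names = tuple(c.removeprefix("overlap_") for c in ov_cols)
    sidecar = path.with_suffix(".snapshots.npz")
    if sidecar.exists():
        with np.load(sidecar, allow_pickle=True) as z:
            snaps = z["W_snapshots"]
            names = tuple(z["overlap_names"].tolist())
    return TrainTrajectory(
        times=df["step"].to_numpy(dtype=int),
        cost=df["cost"].to_numpy(),
        bss_error_per_context=df[bss_cols].to_numpy(),
        overlaps=df[ov_cols].to_numpy(),
        overlap_names=names,
        W_snapshots=snaps,
    )


FIXTURE_NAMES = ("tiny_two_context", "tiny_single_context", "rank_deficient")


def make_fixture(name: str, seed: int = 0) -> dict:
    """Miniature, fully seeded problem instances for fast tests."""
    if name == "tiny_two_context":
        a = (
            sample_mixing_matrix(6, 2, seed=seed * 100 + 1),
            sample_mixing_matrix(6, 2, seed=seed * 100 + 2),
        )
        return dict(
            mixing=MixingModel(kind="per_context", matrices=a),
            schedule=make_context_schedule(2, 40, 500, mode="alternating"),
            net=init_network(2, 6, seed=seed, scale=0.1),
            sampler=laplace_sampler(2),
            prior=laplace_prior(),
            cfg=TrainConfig(eta=1e-3, batch_size=100, n_steps=20_000,
                            record_every=500),
        )
    if name == "tiny_single_context":
        a = (sample_mixing_matrix(4, 2, seed=seed * 100 + 1),)
        return dict(
            mixing=MixingModel(kind="static", matrices=a),
            schedule=None,
            net=init_network(2, 4, seed=seed, scale=0.1),
            sampler=laplace_sampler(2),
            prior=laplace_prior(),
            cfg=TrainConfig(eta=1e-3, batch_size=100, n_steps=4000,
                            record_every=500),
        )
    if name == "rank_deficient":
        rng = np.random.default_rng(seed)
        # C * N_s = 4 columns in a 2-row block: rank can be at most 2
        return dict(A_list=[rng.normal(size=(2, 2)), rng.normal(size=(2, 2))])
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
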