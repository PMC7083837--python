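"""Synthetic trajectory generator: Markovian rotamer dynamics with
per-state emissions and pose-mixture coordinate ensembles.

Real MD trajectories of the transporter are far beyond desk scale, but the
statistics applied to them (rotamer histograms, transition rates, bootstrap
pairwise RMSD) only assume a stationary categorical state process with
state-conditional emissions.  This module provides exactly that generative
structure: a continuous-time Markov chain over side-chain rotamer states
(gauche+/gauche−/trans), simulated exactly as a jump process and discretized
at the frame interval; wrapped-Gaussian dihedral emissions; Gaussian distance
emissions; and two-pose coordinate mixtures with iid jitter for RMSD work.

Units: rates in µs⁻¹, durations in µs, frame intervals in ns (1 µs = 1000 ns),
angles in degrees wrapped to (−180, 180], coordinates/distances in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "RotamerCTMC",
    "StateSeries",
    "JumpPath",
    "FrameEnsemble",
    "stationary_distribution",
    "simulate_jump_process",
    "discretize_jump_path",
    "simulate_ctmc",
    "emit_dihedrals",
    "emit_distances",
    "generate_pose_ensemble",
    "wrap_angle",
]

DEFAULT_STATES = ("gauche+", "gauche-", "trans")
DEFAULT_STATE_ANGLES = (60.0, -60.0, 180.0)


def wrap_angle(angle):
    """Wrap angles in degrees to the interval (−180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class RotamerCTMC:
    """Continuous-time Markov chain over rotamer states with per-state
    dihedral emission parameters.

    ``q_matrix`` is the generator in µs⁻¹: off-diagonals are jump rates,
    rows sum to zero.  ``state_angles`` are the emission means (degrees) and
    ``angle_sd`` the wrapped-Gaussian spread; ``frame_interval`` (ns) is the
    sampling interval used when the jump process is discretized into frames.
    """

    q_matrix: np.ndarray
    states: tuple = DEFAULT_STATES
    state_angles: tuple = DEFAULT_STATE_ANGLES
    angle_sd: float = 15.0
    frame_interval: float = 1.0  # ns

    def __post_init__(self) -> None:
        q = np.asarray(self.q_matrix, dtype=float)
        n = len(self.states)
        if q.shape != (n, n):
            raise ValueError(f"q_matrix must be {n}x{n} to match states")
        off = q[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.any(np.abs(q.sum(axis=1)) > 1e-12):
            raise ValueError("q_matrix rows must sum to zero")
        if len(self.state_angles) != n:
            raise ValueError("state_angles must match states in length")
        if self.angle_sd < 0 or self.frame_interval <= 0:
            raise ValueError("angle_sd must be ≥ 0 and frame_interval > 0")
        object.__setattr__(self, "q_matrix", q)


@dataclass
class StateSeries:
    """Per-frame categorical state labels at a fixed frame interval (ns)."""

    states: np.ndarray
    frame_interval: float
    trajectory_id: str = "traj0"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.size == 0:
            raise ValueError("state series must be nonempty")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def duration_us(self) -> float:
        """Observed span (n−1 intervals) in µs."""
        return (self.states.size - 1) * self.frame_interval / 1000.0


@dataclass
class JumpPath:
    """Exact jump-process realization: state entered at each jump time (µs),
    starting state at t=0, total duration (µs)."""

    jump_times: np.ndarray
    jump_states: np.ndarray  # state index entered at each jump
    initial_state: int
    duration_us: float

    @property
    def n_jumps(self) -> int:
        return int(self.jump_times.size)


@dataclass
class FrameEnsemble:
    """Per-frame coordinates (n_frames, n_atoms, 3) of a named atom set."""

    frames: np.ndarray
    atom_names: tuple
    condition: str = ""
    residue_names: tuple | None = None
    residue_ids: tuple | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.atom_names):
            raise ValueError("atom_names must match the per-frame atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def stationary_distribution(q_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution π solving πQ = 0, Σπ = 1.

    Raises for a reducible chain (states unreachable from one another).
    """
    q = np.asarray(q_matrix, dtype=float)
    n = q.shape[0]
    adj = (q > 0).astype(int)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp > 1:
        raise ValueError("rate matrix is reducible; stationary distribution not unique")
    # solve Q^T π = 0 with the normalization row appended
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_jump_process(
    model: RotamerCTMC, duration_us: float, seed: int = 0, initial_state: int | None = None
) -> JumpPath:
    """Exact (Gillespie) simulation of the CTMC jump process.

    Holding times are exponential with rate −q_ii; the next state is drawn
    from the normalized off-diagonal row.  The initial state is drawn from
    the stationary distribution unless given.
    """
    if duration_us <= 0:
        raise ValueError("duration must be positive")
    q = model.q_matrix
    n = q.shape[0]
    rng = np.random.default_rng(seed)
    if initial_state is None:
        exit_rates = -np.diag(q)
        if np.all(exit_rates == 0):
            initial_state = int(rng.integers(n))
        else:
            initial_state = int(rng.choice(n, p=stationary_distribution(q)))
    times, states = [], []
    s = initial_state
    t = 0.0
    while True:
        rate = -q[s, s]
        if rate <= 0:
            break  # absorbing: holds forever
        t += rng.exponential(1.0 / rate)
        if t >= duration_us:
            break
        p = q[s].copy()
        p[s] = 0.0
        p /= p.sum()
        s = int(rng.choice(n, p=p))
        times.append(t)
        states.append(s)
    return JumpPath(
        jump_times=np.asarray(times, dtype=float),
        jump_states=np.asarray(states, dtype=int),
        initial_state=initial_state,
        duration_us=float(duration_us),
    )


def discretize_jump_path(path: JumpPath, frame_interval_ns: float) -> np.ndarray:
    """State index occupied at each frame time 0, Δt, 2Δt, … within the path
    duration (Δt in ns)."""
    if frame_interval_ns <= 0:
        raise ValueError("frame_interval must be positive")
    dt_us = frame_interval_ns / 1000.0
    n_frames = int(np.floor(path.duration_us / dt_us)) + 1
    frame_times = np.arange(n_frames) * dt_us
    # state at time t: number of jumps with jump_time <= t indexes the path
    idx = np.searchsorted(path.jump_times, frame_times, side="right")
    seq = np.concatenate(([path.initial_state], path.jump_states))
    return seq[idx]


def simulate_ctmc(
    model: RotamerCTMC, duration_us: float, seed: int = 0,
    initial_state: int | None = None, trajectory_id: str = "traj0",
) -> StateSeries:
    """Simulate the CTMC and discretize at the model's frame interval."""
    path = simulate_jump_process(model, duration_us, seed=seed, initial_state=initial_state)
    idx = discretize_jump_path(path, model.frame_interval)
    labels = np.asarray(model.states, dtype=object)[idx]
    return StateSeries(states=labels, frame_interval=model.frame_interval,
                       trajectory_id=trajectory_id)


def emit_dihedrals(series: StateSeries, model: RotamerCTMC, seed: int = 0) -> np.ndarray:
    """Per-frame dihedral (degrees): state mean + wrapped Gaussian(angle_sd)."""
    lut = dict(zip(model.states, model.state_angles))
    unknown = set(np.unique(series.states)) - set(model.states)
    if unknown:
        raise ValueError(f"unknown state labels: {sorted(unknown)}")
    means = np.asarray([lut[s] for s in series.states], dtype=float)
    rng = np.random.default_rng(seed)
    raw = means + model.angle_sd * rng.standard_normal(means.size)
    return wrap_angle(raw)


def emit_distances(series: StateSeries, per_state_mean_sd: dict, seed: int = 0) -> np.ndarray:
    """Per-frame distance (Å): state-conditional Gaussian, truncated at 0.

    ``per_state_mean_sd`` maps state label → (mean, sd).
    """
    unknown = set(np.unique(series.states)) - set(per_state_mean_sd)
    if unknown:
        raise ValueError(f"unknown state labels: {sorted(unknown)}")
    for s, (m, sd) in per_state_mean_sd.items():
        if sd < 0:
            raise ValueError(f"negative sd for state {s!r}")
    means = np.asarray([per_state_mean_sd[s][0] for s in series.states], dtype=float)
    sds = np.asarray([per_state_mean_sd[s][1] for s in series.states], dtype=float)
    rng = np.random.default_rng(seed)
    return np.maximum(means + sds * rng.standard_normal(means.size), 0.0)


def generate_pose_ensemble(
    base_coords: np.ndarray,
    alt_rotation: np.ndarray,
    alt_translation: np.ndarray,
    p_alt: float,
    jitter_sd: float,
    n_frames: int,
    seed: int = 0,
    atom_names: tuple | None = None,
    condition: str = "",
    moving_selection=None,
) -> FrameEnsemble:
    """Two-pose coordinate mixture: each frame is the base pose or its rigid
    transform (probability ``p_alt``), plus iid Gaussian coordinate jitter.

    ``moving_selection`` restricts the rigid transform to a subset of atoms
    (e.g. a ligand displaced within a fixed protein frame); the remaining
    atoms are identical between the two poses.
    """
    base = np.asarray(base_coords, dtype=float)
    if base.ndim != 2 or base.shape[1] != 3:
        raise ValueError("base_coords must have shape (n_atoms, 3)")
    R = np.asarray(alt_rotation, dtype=float)
    tvec = np.asarray(alt_translation, dtype=float)
    if R.shape != (3, 3) or tvec.shape != (3,):
        raise ValueError("alt transform must be a 3x3 rotation and length-3 translation")
    if not 0 <= p_alt <= 1:
        raise ValueError("p_alt must lie in [0, 1]")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    alt = base.copy()
    msel = np.arange(base.shape[0]) if moving_selection is None else np.asarray(moving_selection)
    alt[msel] = base[msel] @ R.T + tvec
    pick = rng.random(n_frames) < p_alt
    frames = np.where(pick[:, None, None], alt[None], base[None]).copy()
    if jitter_sd > 0:
        frames += jitter_sd * rng.standard_normal(frames.shape)
    names = tuple(atom_names) if atom_names is not None else tuple(
        f"A{i}" for i in range(base.shape[0])
    )
    return FrameEnsemble(frames=frames, atom_names=names, condition=condition)
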