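"""Master-equation propagation and exact stochastic simulation.

The folding graph defines a continuous-time Markov chain.  Its generator Q
(column convention: dp/dt = Q p, with Q[j, i] the rate of i -> j) is assembled
once and the population vector is propagated either through the matrix
exponential (exact for this linear, time-homogeneous system) or through a
stiff-capable ODE integrator.  An event-driven Gillespie sampler over the same
graph serves as the independent stochastic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import SimulationError
from .model import KineticModel


@dataclass
class Trajectory:
    """Deterministic solution of the master equation.

    ``populations`` has shape (n_states, n_times); every column is a
    probability distribution over states.
    """

    times: np.ndarray
    populations: np.ndarray
    state_ids: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        if self.populations.shape != (len(self.state_ids), self.times.size):
            raise ValueError("populations must be (n_states, n_times)")

    def population_of(self, state_id: str) -> np.ndarray:
        return self.populations[self.state_ids.index(state_id)]

    def check_conservation(self, tol: float = 1e-8) -> None:
        col = self.populations.sum(axis=0)
        worst = float(np.max(np.abs(col - 1.0)))
        if worst > tol:
            raise SimulationError(f"probability not conserved: max |sum-1| = {worst:.3e}")
        if self.populations.min() < -1e-12 or self.populations.max() > 1 + 1e-12:
            raise SimulationError("population outside [0, 1] beyond tolerance")


def assemble_generator(model: KineticModel) -> np.ndarray:
    """Square rate matrix Q of the chain (1/s), column convention.

    Off-diagonal entry (j, i) is the rate of transition i -> j; the diagonal
    entry of a state is minus its total exit rate, so columns of non-absorbing
    states sum to zero and absorbing columns are identically zero.  Duplicate
    (source, target) pairs are rejected during model validation.
    """
    n = model.n_states
    q = np.zeros((n, n))
    for tr in model.transitions:
        i = model.index[tr.source]
        j = model.index[tr.target]
        q[j, i] = tr.rate
        q[i, i] -= tr.rate
    return q


def _validate_inputs(model: KineticModel, p0: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p0 = np.asarray(p0, dtype=float)
    times = np.asarray(times, dtype=float)
    if p0.shape != (model.n_states,):
        raise SimulationError(f"p0 must have length {model.n_states}, got {p0.shape}")
    if abs(p0.sum() - 1.0) > 1e-9 or p0.min() < 0:
        raise SimulationError("p0 must be a probability distribution")
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise SimulationError("times must be increasing and start at t >= 0")
    return p0, times


def propagate(
    model: KineticModel,
    p0: np.ndarray | None = None,
    times: np.ndarray | None = None,
    method: str = "expm",
) -> Trajectory:
    """Solve dp/dt = Q p from ``p0`` on the requested time grid.

    ``method="expm"`` steps the grid with scaling-and-squaring matrix
    exponentials (exact to round-off); ``method="ode"`` integrates with a
    stiff BDF scheme using the analytic Jacobian Q.  Both satisfy probability
    conservation to 1e-8 and agree to 1e-6 on the default models.
    """
    if p0 is None:
        p0 = model.initial_distribution()
    if times is None:
        if model.config is None:
            raise SimulationError("no time grid given and model carries no config")
        times = model.config.time_grid
    p0, times = _validate_inputs(model, p0, times)
    q = assemble_generator(model)

    if method == "expm":
        pops = np.empty((model.n_states, times.size))
        # cache propagators for repeated step sizes (uniform grids need one expm)
        cache: dict[float, np.ndarray] = {}
        p = p0.copy()
        prev_t = 0.0
        for k, t in enumerate(times):
            dt = float(t - prev_t)
            if dt > 0:
                key = round(dt, 12)
                if key not in cache:
                    cache[key] = expm(q * dt)
                p = cache[key] @ p
            pops[:, k] = p
            prev_t = t
    elif method == "ode":
        rtol = model.config.rtol if model.config else 1e-8
        atol = model.config.atol if model.config else 1e-12
        sol = solve_ivp(
            lambda _t, p: q @ p,
            (0.0, float(times[-1])),
            p0,
            method="BDF",
            t_eval=times,
            jac=lambda _t, _p: q,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success or np.any(~np.isfinite(sol.y)):
            exits = -np.diag(q)
            raise SimulationError(
                "stiff integration failed: "
                f"{sol.message}; n_states={model.n_states}, "
                f"rate range [{exits[exits > 0].min():.3g}, {exits.max():.3g}] 1/s"
            )
        pops = sol.y
    else:
        raise SimulationError(f"unknown propagation method {method!r}")

    traj = Trajectory(times=times, populations=pops, state_ids=[s.id for s in model.states])
    traj.check_conservation(tol=1e-8 if method == "expm" else 1e-7)
    return traj


@dataclass
class SSAResult:
    """Monte-Carlo estimate of the state populations at fixed query times."""

    times: np.ndarray
    populations: np.ndarray  # (n_states, n_times) fraction of trajectories
    standard_errors: np.ndarray  # binomial SE of each fraction
    n_traj: int
    state_ids: list[str]
    absorption_times: np.ndarray  # per-trajectory entry time into an absorbing state (nan if none)

    def population_of(self, state_id: str) -> np.ndarray:
        return self.populations[self.state_ids.index(state_id)]


def simulate_ssa(
    model: KineticModel,
    p0: np.ndarray | None = None,
    times: np.ndarray | None = None,
    n_traj: int = 10_000,
    seed: int = 0,
) -> SSAResult:
    """Exact event-driven sampling of the chain (Gillespie algorithm).

    All transitions are first order, so trajectories advance in lock-step over
    jump rounds: every active trajectory draws an exponential dwell from its
    current state's total exit rate and then a categorical jump.  Identical
    seeds give bitwise-identical results; estimates converge to
    :func:`propagate` as ``n_traj`` grows.
    """
    if n_traj < 1:
        raise SimulationError("n_traj must be >= 1")
    if p0 is None:
        p0 = model.initial_distribution()
    if times is None:
        if model.config is None:
            raise SimulationError("no query times given and model carries no config")
        times = model.config.time_grid
    p0, times = _validate_inputs(model, p0, times)

    q = assemble_generator(model)
    n = model.n_states
    exit_rate = -np.diag(q)
    jump = q.copy()
    np.fill_diagonal(jump, 0.0)
    cum_prob = np.zeros_like(jump.T)
    targets_ok = exit_rate > 0
    cum_prob[targets_ok] = np.cumsum(jump.T[targets_ok] / exit_rate[targets_ok, None], axis=1)

    rng = np.random.default_rng(seed)
    state = rng.choice(n, size=n_traj, p=p0)
    t_entry = np.zeros(n_traj)
    absorbed_at = np.full(n_traj, np.nan)
    snap = np.full((times.size, n_traj), -1, dtype=np.int64)

    active = targets_ok[state]
    absorbed_at[~active] = 0.0
    for qi, tq in enumerate(times):  # states occupied at t=... for already-absorbed starts
        snap[qi, ~active] = state[~active]

    max_rounds = 100 * n + 1000  # defensive bound; default chains absorb in ~n jumps
    for _ in range(max_rounds):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        lam = exit_rate[state[idx]]
        dwell = rng.exponential(1.0, size=idx.size) / lam
        t_exit = t_entry[idx] + dwell
        # record snapshots covered by this dwell
        for qi, tq in enumerate(times):
            hit = (t_entry[idx] <= tq) & (tq < t_exit)
            snap[qi, idx[hit]] = state[idx[hit]]
        # categorical jump, grouped by current state for vectorized searchsorted
        u = rng.random(idx.size)
        new_state = np.empty(idx.size, dtype=np.int64)
        order = np.argsort(state[idx], kind="stable")
        s_sorted = state[idx][order]
        bounds = np.flatnonzero(np.diff(s_sorted)) + 1
        for grp in np.split(order, bounds):
            s = state[idx[grp[0]]]
            new_state[grp] = np.searchsorted(cum_prob[s], u[grp], side="right")
        np.minimum(new_state, n - 1, out=new_state)  # guard against cum-sum round-off
        state[idx] = new_state
        t_entry[idx] = t_exit
        now_absorbed = ~targets_ok[new_state]
        absorbed_at[idx[now_absorbed]] = t_exit[now_absorbed]
        # absorbed trajectories occupy their final state at all later query times
        done = idx[now_absorbed]
        if done.size:
            for qi, tq in enumerate(times):
                hit = t_entry[done] <= tq
                snap[qi, done[hit]] = state[done[hit]]
        active[idx] = targets_ok[new_state]
    else:  # pragma: no cover - defensive
        raise SimulationError("SSA exceeded the jump-round bound; model may be non-absorbing")

    if snap.min() < 0:  # pragma: no cover - defensive
        raise SimulationError("internal error: unassigned SSA snapshot")
    pops = np.empty((n, times.size))
    for qi in range(times.size):
        pops[:, qi] = np.bincount(snap[qi], minlength=n) / n_traj
    se = np.sqrt(pops * (1.0 - pops) / n_traj)
    return SSAResult(
        times=times,
        populations=pops,
        standard_errors=se,
        n_traj=n_traj,
        state_ids=[s.id for s in model.states],
        absorption_times=absorbed_at,
    )
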