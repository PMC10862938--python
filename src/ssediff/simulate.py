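"""Stochastic path simulation of state counts and frequencies.

Two complementary simulators are provided:

* Euler–Maruyama discretizations of the count SDE
  ``dN_i = mu_i dt + sigma_i dW`` and of the derived frequency SDE, with the
  drift/variance recomputed from the current state at every step, negative
  count excursions clamped to zero, and frequencies renormalized onto the
  simplex each step;
* an exact continuous-time Markov jump process over integer count vectors
  (Gillespie algorithm) whose event rates are exactly the per-state gain and
  loss totals — the tree-free reference process against which the diffusion
  is validated.

Both are seeded and bit-reproducible.  Ensembles of replicate paths are
summarized by per-state terminal means, sample variances and normal 95%
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .event_rates import rate_matrices
from .diffusion import TotalExtinctionError
from .state_space import GeoSSEParams, StateSpace

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class Trajectory:
    """A single simulated path: time grid plus per-state series."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_states)
    kind: str  # "counts" | "frequencies"
    labels: Tuple[str, ...]
    seed: Optional[int] = None

    @property
    def terminal(self) -> np.ndarray:
        return self.values[-1]


@dataclass
class EnsembleSummary:
    """Terminal-value summary across replicate paths."""

    labels: Tuple[str, ...]
    terminal_values: np.ndarray  # (replicates, n_states)
    mean: np.ndarray = field(init=False)
    variance: np.ndarray = field(init=False)
    ci_lower: np.ndarray = field(init=False)
    ci_upper: np.ndarray = field(init=False)
    times: Optional[np.ndarray] = None
    mean_path: Optional[np.ndarray] = None  # (n_times, n_states)

    def __post_init__(self):
        vals = np.asarray(self.terminal_values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 replicates")
        self.terminal_values = vals
        self.mean = vals.mean(axis=0)
        self.variance = vals.var(axis=0, ddof=1)
        half = _Z95 * np.sqrt(self.variance / vals.shape[0])
        self.ci_lower = self.mean - half
        self.ci_upper = self.mean + half

    @property
    def n_replicates(self) -> int:
        return self.terminal_values.shape[0]


def counts_from_frequencies(
    pi0, N0: int, method: str = "largest_remainder", rng=None
) -> np.ndarray:
    """Integer initial counts realizing frequencies ``pi0`` at total ``N0``.

    ``largest_remainder`` deterministically rounds N0*pi0 so the total is
    exact; ``multinomial`` draws from Multinomial(N0, pi0) with ``rng``.
    """
    pi = np.asarray(pi0, dtype=float)
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi0 must be a normalized frequency vector")
    if method == "multinomial":
        rng = np.random.default_rng(rng)
        return rng.multinomial(N0, pi / pi.sum()).astype(float)
    if method != "largest_remainder":
        raise ValueError(f"unknown rounding method {method!r}")
    raw = pi * N0
    base = np.floor(raw)
    short = int(round(N0 - base.sum()))
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def _drift_and_var(counts2d: np.ndarray, Gp: np.ndarray, Gm: np.ndarray):
    plus = counts2d @ Gp.T
    minus = counts2d @ Gm.T
    return plus - minus, plus + minus


def _warn_if_step_too_coarse(total_rate: float, dt: float) -> None:
    if total_rate * dt > 0.1:
        warnings.warn(
            f"per-step event load {total_rate * dt:.3f} exceeds 0.1; "
            "consider more time steps for this horizon",
            RuntimeWarning,
            stacklevel=3,
        )


def simulate_count_paths(
    params: GeoSSEParams,
    space: StateSpace,
    n0,
    T: float,
    n_steps: int,
    seed=None,
    n_paths: int = 1,
) -> np.ndarray:
    """Euler–Maruyama count paths; returns array (n_paths, n_steps+1, S).

    Each state receives an independent Wiener increment per step; any state
    driven below zero is clamped to exactly zero before the next step.
    """
    n0 = np.asarray(n0, dtype=float)
    if np.any(n0 < 0):
        raise ValueError("initial counts must be nonnegative")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    Gp, Gm = rate_matrices(params, space)
    S = space.n_states
    dt = T / n_steps
    sqdt = np.sqrt(dt)
    out = np.empty((n_paths, n_steps + 1, S))
    cur = np.broadcast_to(n0, (n_paths, S)).copy()
    out[:, 0] = cur
    warned = False
    for step in range(n_steps):
        mu, s2 = _drift_and_var(cur, Gp, Gm)
        if not warned and np.max(s2, initial=0.0) * dt > 0.1:
            _warn_if_step_too_coarse(float(np.max(s2)), dt)
            warned = True
        noise = rng.standard_normal((n_paths, S))
        cur = cur + mu * dt + np.sqrt(s2) * sqdt * noise
        np.maximum(cur, 0.0, out=cur)
        out[:, step + 1] = cur
    return out


def simulate_count_path(
    params: GeoSSEParams,
    space: StateSpace,
    n0,
    T: float,
    n_steps: int,
    seed=None,
) -> Trajectory:
    """Single Euler–Maruyama count path as a :class:`Trajectory`."""
    vals = simulate_count_paths(params, space, n0, T, n_steps, seed, n_paths=1)[0]
    return Trajectory(
        times=np.linspace(0.0, T, n_steps + 1),
        values=vals,
        kind="counts",
        labels=space.labels(),
        seed=seed if isinstance(seed, int) else None,
    )


def _frequency_step_params(counts2d: np.ndarray, mu, s2):
    """Vectorized frequency drift/variance (rows = paths)."""
    N = counts2d.sum(axis=1, keepdims=True)
    pi = counts2d / N
    correction = np.sum(-mu + s2 / N, axis=1, keepdims=True)
    mu_pi = (mu - s2 / N) / N + pi / N * correction
    sigma2_pi = (s2 / N**2) * (1 - 2 * pi) + (pi / N) ** 2 * s2.sum(
        axis=1, keepdims=True
    )
    return mu_pi, sigma2_pi


def simulate_frequency_paths(
    params: GeoSSEParams,
    space: StateSpace,
    n0,
    T: float,
    n_steps: int,
    seed=None,
    n_paths: int = 1,
) -> np.ndarray:
    """Euler–Maruyama frequency paths; returns (n_paths, n_steps+1, S).

    Per step: the latent count vector is advanced first and clamped at zero;
    the frequency drift/variance are then evaluated at the updated counts and
    the frequency vector advanced, truncated to [0, 1] and renormalized to
    sum 1.  Raises :class:`TotalExtinctionError` (with the time stamp) if any
    path's total count hits zero.
    """
    n0 = np.asarray(n0, dtype=float)
    if np.any(n0 < 0):
        raise ValueError("initial counts must be nonnegative")
    if n0.sum() <= 0:
        raise ValueError("initial total count must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    Gp, Gm = rate_matrices(params, space)
    S = space.n_states
    dt = T / n_steps
    sqdt = np.sqrt(dt)
    counts = np.broadcast_to(n0, (n_paths, S)).copy()
    pi = counts / counts.sum(axis=1, keepdims=True)
    out = np.empty((n_paths, n_steps + 1, S))
    out[:, 0] = pi
    for step in range(n_steps):
        mu, s2 = _drift_and_var(counts, Gp, Gm)
        counts = counts + mu * dt + np.sqrt(s2) * sqdt * rng.standard_normal(
            (n_paths, S)
        )
        np.maximum(counts, 0.0, out=counts)
        if np.any(counts.sum(axis=1) <= 0):
            raise TotalExtinctionError(
                f"total count reached 0 at t = {(step + 1) * dt:.6g}"
            )
        mu_c, s2_c = _drift_and_var(counts, Gp, Gm)
        mu_pi, s2_pi = _frequency_step_params(counts, mu_c, s2_c)
        pi = pi + mu_pi * dt + np.sqrt(s2_pi) * sqdt * rng.standard_normal(
            (n_paths, S)
        )
        np.clip(pi, 0.0, 1.0, out=pi)
        pi = pi / pi.sum(axis=1, keepdims=True)
        out[:, step + 1] = pi
    return out


def simulate_frequency_path(
    params: GeoSSEParams,
    space: StateSpace,
    n0,
    T: float,
    n_steps: int,
    seed=None,
) -> Trajectory:
    """Single Euler–Maruyama frequency path as a :class:`Trajectory`."""
    vals = simulate_frequency_paths(
        params, space, n0, T, n_steps, seed, n_paths=1
    )[0]
    return Trajectory(
        times=np.linspace(0.0, T, n_steps + 1),
        values=vals,
        kind="frequencies",
        labels=space.labels(),
        seed=seed if isinstance(seed, int) else None,
    )


def _build_event_table(params: GeoSSEParams, space: StateSpace):
    """Enumerate every elementary event: (source state, rate constant,
    count-change vector)."""
    S = space.n_states
    src, coeff, deltas = [], [], []

    def add(source, rate, changes):
        if rate <= 0:
            return
        delta = np.zeros(S)
        for st, ch in changes:
            delta[space.index(st)] += ch
        src.append(space.index(source))
        coeff.append(rate)
        deltas.append(delta)

    from .state_space import RangeState

    for j in space.states:
        # within-region speciation: new endemic daughter in region l
        for l in j:
            add(j, params.w[l], [(RangeState([l]), +1)])
        # dispersal into a region outside the current range
        if len(j) < space.n_regions:
            for l in space.regions:
                if l in j:
                    continue
                rate = sum(params.d[(k, l)] for k in j)
                add(j, rate, [(j, -1), (j.union(l), +1)])
        # between-region speciation: parent replaced by the two daughters
        for left, right in space.splits(j):
            add(
                j,
                params.b_rate(left.regions, right.regions),
                [(j, -1), (left, +1), (right, +1)],
            )
        # local extinction: drop one region (or the species, if endemic)
        for l in j:
            if len(j) == 1:
                add(j, params.e[l], [(j, -1)])
            else:
                add(j, params.e[l], [(j, -1), (j.minus(l), +1)])

    if not src:
        return np.zeros(0, dtype=int), np.zeros(0), np.zeros((0, S))
    return np.array(src), np.array(coeff), np.array(deltas)


def simulate_jump_process(
    params: GeoSSEParams,
    space: StateSpace,
    n0,
    T: float,
    seed=None,
    condition_on_survival: bool = False,
    max_rejections: int = 10_000,
) -> Trajectory:
    """Exact Markov jump-process path of integer state counts.

    Events fire with exponential waiting times at the aggregate of all
    elementary event rates; one event is chosen proportionally to its rate
    and its increments applied.  With ``condition_on_survival`` paths ending
    in total extinction are rejected and redrawn; the rejection count is
    stored on the returned trajectory as ``.rejections``.
    """
    n0_arr = np.asarray(n0, dtype=float)
    if np.any(n0_arr < 0) or np.any(n0_arr != np.round(n0_arr)):
        raise ValueError("jump-process initial counts must be nonnegative integers")
    rng = np.random.default_rng(seed)
    src, coeff, deltas = _build_event_table(params, space)

    rejections = 0
    while True:
        times = [0.0]
        values = [n0_arr.copy()]
        t = 0.0
        n = n0_arr.copy()
        while True:
            rates = coeff * n[src]
            total = rates.sum()
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= T:
                break
            k = np.searchsorted(np.cumsum(rates), rng.random() * total)
            n = n + deltas[k]
            times.append(t)
            values.append(n.copy())
        times.append(T)
        values.append(n.copy())
        if not condition_on_survival or n.sum() > 0:
            break
        rejections += 1
        if rejections > max_rejections:
            raise RuntimeError(
                "survival conditioning exceeded the rejection budget"
            )

    traj = Trajectory(
        times=np.array(times),
        values=np.array(values),
        kind="counts",
        labels=space.labels(),
        seed=seed if isinstance(seed, int) else None,
    )
    traj.rejections = rejections
    return traj


def spawn_seeds(seed, n: int) -> Sequence[np.random.SeedSequence]:
    """Deterministically spawn ``n`` child seeds from one master seed."""
    return np.random.SeedSequence(seed).spawn(n)


def ensemble(
    run: Callable[[object], Trajectory],
    replicates: int,
    seed=None,
) -> EnsembleSummary:
    """Run ``replicates`` seeded paths and summarize their terminal values.

    ``run`` maps a child seed to a :class:`Trajectory`.  Per-time-point mean
    paths are attached when all replicates share an identical time grid.
    """
    if replicates < 2:
        raise ValueError("an ensemble needs at least 2 replicates")
    trajs = [run(s) for s in spawn_seeds(seed, replicates)]
    terminal = np.array([t.terminal for t in trajs])
    summary = EnsembleSummary(labels=trajs[0].labels, terminal_values=terminal)
    t0 = trajs[0].times
    if all(
        t.times.shape == t0.shape and np.array_equal(t.times, t0) for t in trajs
    ):
        summary.times = t0
        summary.mean_path = np.mean([t.values for t in trajs], axis=0)
    return summary


def diffusion_count_ensemble(
    params, space, n0, T, n_steps, replicates, seed=None
) -> EnsembleSummary:
    """Vectorized Euler–Maruyama count ensemble (all replicates at once)."""
    paths = simulate_count_paths(
        params, space, n0, T, n_steps, seed, n_paths=replicates
    )
    summary = EnsembleSummary(
        labels=space.labels(), terminal_values=paths[:, -1, :]
    )
    summary.times = np.linspace(0.0, T, n_steps + 1)
    summary.mean_path = paths.mean(axis=0)
    return summary


def jump_ensemble(
    params, space, n0, T, replicates, seed=None, condition_on_survival=False
) -> EnsembleSummary:
    """Jump-process ensemble summarized at the terminal time."""
    terminal = np.empty((replicates, space.n_states))
    for r, s in enumerate(spawn_seeds(seed, replicates)):
        traj = simulate_jump_process(
            params, space, n0, T, s, condition_on_survival
        )
        terminal[r] = traj.terminal
    return EnsembleSummary(labels=space.labels(), terminal_values=terminal)
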