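"""Deterministic large-population theory: frequency ODE, closed forms,
stationary frequencies, rate solving, and mixing times.

In the large-population limit the state-frequency dynamics are deterministic:
``dPi_i/dt`` equals the per-capita gain/loss difference.  Because every gain
and loss total is linear in the frequencies, substituting the simplex
constraint ``Pi_last = 1 - sum(others)`` turns the dynamics into an affine
linear system ``dx/dt = J x + c`` in the remaining |S|-1 frequencies, solved
here three ways:

* numerically (stiff-capable ODE integration on a uniform grid);
* in closed form for the 2-region model (eigen-decomposition of the 2x2
  affine system, with the transparently-recorded textbook constants);
* via the projection-matrix route: the dominant right eigenvector of the
  full linear count-dynamics matrix, normalized to sum 1 (the stable stage
  distribution of population biology).

The reduced-system fixed point and the dominant eigenvector generally differ
slightly unless the net growth rate is zero; both are exposed.

The inverse problem — find strictly positive rates whose stationary
frequencies match a given target — is linear in the rates at a fixed target,
so it is solved as a linear program with randomized objective restarts;
distinct restarts exhibit the many-to-one map from rates to stationary
frequencies.  A mixing time per state is the first grid time at which the
successive change of that state's frequency drops below a threshold epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import linprog

from .event_rates import count_drift_matrix, flux_total
from .simulate import Trajectory
from .state_space import (
    GeoSSEParams,
    StateSpace,
    enumerate_range_states,
    required_split_keys,
    split_key,
    validate_params,
)

__all__ = [
    "reduced_affine_system",
    "integrate_frequency_ode",
    "stationary_by_ode",
    "Stationary2RegionSolution",
    "solve_stationary_2region",
    "stationary_by_eigen",
    "RateSolution",
    "solve_rates_for_frequencies",
    "verify_rates_for_frequencies",
    "sample_equal_thirds_rates",
    "MixingTimes",
    "time_to_stationarity",
]


def _check_pi0(pi0, n_states: int) -> np.ndarray:
    pi = np.asarray(pi0, dtype=float)
    if pi.shape != (n_states,):
        raise ValueError(f"pi0 must have shape ({n_states},), got {pi.shape}")
    if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi0 must be a normalized frequency vector")
    return pi


def reduced_affine_system(params: GeoSSEParams, space: StateSpace):
    """Affine system dx/dt = J x + c for the first |S|-1 frequencies, with
    the last (full-range) state eliminated by Pi_last = 1 - sum(x)."""
    M = count_drift_matrix(params, space)
    S = space.n_states
    J = M[: S - 1, : S - 1] - M[: S - 1, S - 1][:, None]
    c = M[: S - 1, S - 1].copy()
    return J, c


def integrate_frequency_ode(
    params: GeoSSEParams,
    space: StateSpace,
    pi0,
    T: float,
    n_grid: int = 1000,
) -> Trajectory:
    """Integrate the deterministic frequency dynamics on a uniform grid.

    Returns all |S| frequency series; the eliminated state is reconstructed
    as one minus the rest, so rows sum to one exactly.
    """
    pi0 = _check_pi0(pi0, space.n_states)
    validate_params(params, space, strict=False)
    J, c = reduced_affine_system(params, space)
    times = np.linspace(0.0, T, n_grid)
    sol = solve_ivp(
        lambda t, x: J @ x + c,
        (0.0, T),
        pi0[:-1],
        t_eval=times,
        method="LSODA",
        rtol=1e-12,
        atol=1e-14,
        jac=lambda t, x: J,
    )
    if not sol.success:  # pragma: no cover - LSODA on a linear system
        raise RuntimeError(f"frequency ODE integration failed: {sol.message}")
    x = sol.y.T
    values = np.column_stack([x, 1.0 - x.sum(axis=1)])
    return Trajectory(
        times=times, values=values, kind="frequencies", labels=space.labels()
    )


def stationary_by_ode(
    params: GeoSSEParams,
    space: StateSpace,
    pi0=None,
    T: float = 2000.0,
    n_grid: int = 2001,
    tol: float = 1e-10,
    max_doublings: int = 6,
) -> np.ndarray:
    """Stationary frequencies as the converged terminal of the frequency ODE.

    Starts from the uniform interior point unless ``pi0`` is given, and
    doubles the horizon until the terminal drift is below ``tol``.
    """
    if pi0 is None:
        pi0 = np.full(space.n_states, 1.0 / space.n_states)
    horizon = T
    for _ in range(max_doublings):
        traj = integrate_frequency_ode(params, space, pi0, horizon, n_grid)
        term = traj.values[-1]
        J, c = reduced_affine_system(params, space)
        drift = J @ term[:-1] + c
        if np.max(np.abs(drift)) < tol:
            return term
        horizon *= 2
    raise RuntimeError(
        f"frequency ODE did not reach stationarity within horizon {horizon}"
    )


@dataclass
class Stationary2RegionSolution:
    """Closed-form solution of the 2-region frequency dynamics.

    ``pi_hat`` holds the stationary frequencies (Pi_A, Pi_B, Pi_AB).  The
    eigenvalues/eigenvectors and integration constants come from the
    eigen-decomposition of the reduced 2x2 affine system; the textbook-style
    scalar constants (numA, denomA, R, R1, R2) are evaluated from their
    analytic forms and recorded for transparency.  ``printed_R1`` keeps the
    uncorrected variant of R1 in which most quartic coefficients were
    typeset without their factor of 4; it is retained for reference only and
    enters no computation.
    """

    pi_hat: np.ndarray
    lambda1: float
    lambda2: float
    nu1: np.ndarray
    nu2: np.ndarray
    C1: float
    C2: float
    K: np.ndarray
    R: float
    R1: float
    R2: float
    numA: float
    denomA: float
    printed_R1: float
    pi0: np.ndarray
    labels: Tuple[str, ...] = ("A", "B", "AB")

    def trajectory(self, times) -> Trajectory:
        """Evaluate Pi(t) = C1 nu1 e^(l1 t) + C2 nu2 e^(l2 t) + K on a grid,
        reconstructing the widespread frequency from the simplex."""
        t = np.asarray(times, dtype=float)
        x = (
            self.C1 * np.outer(np.exp(self.lambda1 * t), self.nu1)
            + self.C2 * np.outer(np.exp(self.lambda2 * t), self.nu2)
            + self.K
        )
        values = np.column_stack([x, 1.0 - x.sum(axis=1)])
        return Trajectory(
            times=t, values=values, kind="frequencies", labels=self.labels
        )

    def simplex_violated(self, times) -> bool:
        """True if Pi_A + Pi_B exceeds 1 anywhere on the grid (the closed
        form's validity proviso)."""
        traj = self.trajectory(times)
        return bool(np.any(traj.values[:, -1] < -1e-12))


def solve_stationary_2region(
    params: GeoSSEParams, pi0=(1 / 3, 1 / 3, 1 / 3)
) -> Stationary2RegionSolution:
    """Closed-form stationary frequencies and trajectory for 2 regions."""
    space = enumerate_range_states(("A", "B"))
    p = validate_params(params, space, strict=False)
    pi0 = _check_pi0(pi0, 3)

    wA, wB = p.w["A"], p.w["B"]
    eA, eB = p.e["A"], p.e["B"]
    dAB, dBA = p.d[("A", "B")], p.d[("B", "A")]
    bBA = p.b[split_key("A", "B")]

    J, c = reduced_affine_system(p, space)
    K = np.linalg.solve(J, -c)
    evals, evecs = np.linalg.eig(J)
    evals = evals.real
    evecs = evecs.real
    order = np.argsort(evals)  # lambda1 = more negative (faster decay)
    lam1, lam2 = evals[order[0]], evals[order[1]]
    nu1 = evecs[:, order[0]]
    nu2 = evecs[:, order[1]]
    C = np.linalg.solve(np.column_stack([nu1, nu2]), pi0[:2] - K)

    # analytic scalar constants (discriminant split into the dispersal part
    # R2 and the remainder R1)
    numA = (wA + bBA + eB) * (eB + dBA - wB)
    denomA = (eA + dAB + bBA + eB) * (eB + dBA + bBA + eA) - (
        wB + bBA + eA
    ) * (wA + bBA + eB)
    R2 = (dAB - dBA) ** 2
    R1 = 4.0 * (bBA + eA + wB) * (bBA + eB + wA)
    R = np.sqrt(R1 + R2)
    printed_R1 = (
        4 * bBA**2
        + 4 * bBA * eA
        + bBA * eB
        + bBA * wA
        + bBA * wB
        + 4 * eA * eB
        + eA * wA
        + eB * wB
        + wA * wB
    )

    pi_hat = np.array([K[0], K[1], 1.0 - K.sum()])
    return Stationary2RegionSolution(
        pi_hat=pi_hat,
        lambda1=float(lam1),
        lambda2=float(lam2),
        nu1=nu1,
        nu2=nu2,
        C1=float(C[0]),
        C2=float(C[1]),
        K=K,
        R=float(R),
        R1=float(R1),
        R2=float(R2),
        numA=float(numA),
        denomA=float(denomA),
        printed_R1=float(printed_R1),
        pi0=pi0,
    )


def stationary_by_eigen(params: GeoSSEParams, space: StateSpace) -> np.ndarray:
    """Stationary frequencies by the projection-matrix method.

    The linear count dynamics dN/dt = A N have long-run direction given by
    the right eigenvector of the eigenvalue with largest real part (dominant
    growth rate); normalized to sum 1 it is the stable state distribution.
    """
    validate_params(params, space, strict=False)
    A = count_drift_matrix(params, space)
    if A.shape == (1, 1):
        return np.array([1.0])
    evals, evecs = np.linalg.eig(A)
    dom = np.argmax(evals.real)
    close = np.abs(evals - evals[dom]) < 1e-10 * max(1.0, np.abs(evals[dom]))
    if close.sum() > 1:
        vecs = evecs[:, close]
        if np.linalg.matrix_rank(vecs, tol=1e-10) < close.sum():
            raise np.linalg.LinAlgError(
                "dominant eigenspace of the count matrix is defective"
            )
    v = evecs[:, dom]
    if np.max(np.abs(v.imag)) > 1e-10:
        raise np.linalg.LinAlgError("dominant eigenvector is not real")
    v = v.real
    v = v / v.sum()
    if np.any(v < -1e-10):
        raise np.linalg.LinAlgError(
            "dominant eigenvector is not sign-definite"
        )
    return np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum()


# ---------------------------------------------------------------------------
# rate-from-frequency solving


def rate_names(space: StateSpace) -> Tuple[str, ...]:
    """Flat naming of the full rate vector: w:R, e:R, d:K>L, b:left|right."""
    names = [f"w:{r}" for r in space.regions]
    names += [f"e:{r}" for r in space.regions]
    names += [
        f"d:{k}>{l}" for k in space.regions for l in space.regions if k != l
    ]
    names += [
        f"b:{''.join(a)}|{''.join(b)}" for a, b in required_split_keys(space)
    ]
    return tuple(names)


def params_from_vector(theta, space: StateSpace) -> GeoSSEParams:
    names = rate_names(space)
    w, e, d, b = {}, {}, {}, {}
    for name, v in zip(names, theta):
        kind, key = name.split(":", 1)
        if kind == "w":
            w[key] = float(v)
        elif kind == "e":
            e[key] = float(v)
        elif kind == "d":
            k, l = key.split(">")
            d[(k, l)] = float(v)
        else:
            left, right = key.split("|")
            b[split_key(tuple(left), tuple(right))] = float(v)
    return GeoSSEParams(w=w, e=e, d=d, b=b)


def _linear_maps(target: np.ndarray, space: StateSpace):
    """Rows of the linear maps theta -> per-state stationary residual and
    theta -> per-state flux (both linear in the rates)."""
    names = rate_names(space)
    n = len(names)
    S = space.n_states
    A_resid = np.zeros((S, n))
    A_flux = np.zeros((S, n))
    for k in range(n):
        theta = np.zeros(n)
        theta[k] = 1.0
        p = params_from_vector(theta, space)
        A_resid[:, k] = count_drift_matrix(p, space) @ target
        A_flux[:, k] = [flux_total(p, s, space) for s in space.states]
    return A_resid, A_flux


@dataclass
class RateSolution:
    """Outcome of rate-from-frequency solving or verification."""

    params: Optional[GeoSSEParams]
    residuals: np.ndarray
    feasible: bool
    target: np.ndarray
    flux: Optional[np.ndarray] = None
    message: str = ""


def verify_rates_for_frequencies(
    params: GeoSSEParams,
    target,
    space: StateSpace,
    tol: float = 1e-8,
    flux_margin: float = 1e-8,
) -> RateSolution:
    """Check whether given rates hold ``target`` stationary and respect the
    flux ordering implied by the ordering of the target frequencies."""
    target = _check_pi0(target, space.n_states)
    p = validate_params(params, space, strict=False)
    resid = count_drift_matrix(p, space) @ target
    flux = np.array([flux_total(p, s, space) for s in space.states])
    ok = bool(np.max(np.abs(resid)) < tol)
    for i in range(space.n_states):
        for j in range(space.n_states):
            if target[i] > target[j] + 1e-12:
                ok = ok and flux[i] > flux[j] - flux_margin
            elif abs(target[i] - target[j]) <= 1e-12 and i < j:
                ok = ok and abs(flux[i] - flux[j]) < max(tol, flux_margin)
    return RateSolution(
        params=p, residuals=resid, feasible=ok, target=target, flux=flux
    )


def solve_rates_for_frequencies(
    target,
    space: StateSpace,
    fixed: Optional[Dict[str, float]] = None,
    bounds: Tuple[float, float] = (1e-4, 1.0),
    seed=None,
    n_restarts: int = 20,
    flux_margin: float = 1e-8,
) -> RateSolution:
    """Find strictly positive rates whose stationary frequencies are
    ``target``.

    At a fixed target the stationarity equalities and the flux-ordering
    side conditions are all linear in the rate vector, so each restart
    solves a linear program with a random objective; the first feasible
    vertex is returned (different seeds typically land on different members
    of the solution family).  ``fixed`` pins named rates (e.g. ``"d:A>B"``)
    to given values.
    """
    target = _check_pi0(target, space.n_states)
    if np.any(target <= 0):
        raise ValueError("target frequencies must be strictly positive")
    rng = np.random.default_rng(seed)
    names = rate_names(space)
    n = len(names)
    lb, ub = bounds
    A_resid, A_flux = _linear_maps(target, space)

    A_ub, b_ub = [], []
    A_eq, b_eq = [A_resid], [np.zeros(space.n_states)]
    for i in range(space.n_states):
        for j in range(i + 1, space.n_states):
            if target[i] > target[j] + 1e-12:
                A_ub.append(A_flux[j] - A_flux[i])
                b_ub.append(-flux_margin)
            elif target[j] > target[i] + 1e-12:
                A_ub.append(A_flux[i] - A_flux[j])
                b_ub.append(-flux_margin)
            else:
                A_eq.append((A_flux[i] - A_flux[j])[None, :])
                b_eq.append(np.zeros(1))
    A_ub = np.array(A_ub) if A_ub else None
    b_ub = np.array(b_ub) if b_ub else None
    A_eq = np.vstack(A_eq)
    b_eq = np.concatenate(b_eq)

    var_bounds = []
    fixed = fixed or {}
    unknown = set(fixed) - set(names)
    if unknown:
        raise KeyError(f"fixed refers to unknown rates: {sorted(unknown)}")
    for name in names:
        if name in fixed:
            var_bounds.append((fixed[name], fixed[name]))
        else:
            var_bounds.append((lb, ub))

    best = None
    for _ in range(max(1, n_restarts)):
        cvec = rng.standard_normal(n)
        res = linprog(
            cvec,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=var_bounds,
            method="highs",
        )
        if res.status == 0:
            p = params_from_vector(res.x, space)
            check = verify_rates_for_frequencies(
                p, target, space, flux_margin=flux_margin / 10
            )
            if check.feasible:
                return RateSolution(
                    params=p,
                    residuals=check.residuals,
                    feasible=True,
                    target=target,
                    flux=check.flux,
                    message="feasible",
                )
            best = check
    if best is None:
        best = RateSolution(
            params=None,
            residuals=np.full(space.n_states, np.inf),
            feasible=False,
            target=target,
            message="no feasible point found",
        )
    best.feasible = False
    return best


def sample_equal_thirds_rates(family: int, seed=None) -> GeoSSEParams:
    """Sample 2-region rates from one of the two closed-form families whose
    stationary frequencies are (1/3, 1/3, 1/3).

    Both families share wA = (-2 bBA + 2 dAB + dBA - 2 eB)/2,
    wB = (2 eB - dAB)/2 and eA = dAB + dBA - bBA - eB; they differ in the
    admissible region of the free rates: family 1 has eB < dAB < 2 eB with
    0 < bBA <= dAB - eB, family 2 has 0 < dAB <= eB with
    dBA > 2 (bBA - dAB + eB).
    """
    rng = np.random.default_rng(seed)
    if family == 1:
        eB = rng.uniform(0.01, 0.3)
        dAB = rng.uniform(eB * 1.05, 2 * eB * 0.95)
        bBA = rng.uniform(0.2, 1.0) * (dAB - eB)
        dBA = rng.uniform(0.05, 1.0)
    elif family == 2:
        eB = rng.uniform(0.01, 0.3)
        dAB = rng.uniform(0.2, 1.0) * eB
        bBA = rng.uniform(0.005, 0.4)
        dBA = 2 * (bBA - dAB + eB) + rng.uniform(0.01, 0.5)
    else:
        raise ValueError("family must be 1 or 2")
    wA = 0.5 * (-2 * bBA + 2 * dAB + dBA - 2 * eB)
    wB = 0.5 * (2 * eB - dAB)
    eA = dAB + dBA - bBA - eB
    return GeoSSEParams(
        w={"A": wA, "B": wB},
        e={"A": eA, "B": eB},
        d={("A", "B"): dAB, ("B", "A"): dBA},
        b={split_key("A", "B"): bBA},
    )


# ---------------------------------------------------------------------------
# mixing time


@dataclass
class MixingTimes:
    """Per-state first grid time at which the successive frequency change
    drops below epsilon; None where the criterion was never met on [0, T]."""

    times: Dict[str, Optional[float]]
    epsilon: float
    dt: float
    T: float


def time_to_stationarity(
    params: GeoSSEParams,
    space: StateSpace,
    pi0,
    T: float,
    n_grid: int = 1000,
    epsilon: float = 1e-9,
) -> MixingTimes:
    """Mixing times on a uniform grid of ``n_grid`` points over [0, T].

    The deterministic frequency trajectory is evaluated via the 2-region
    closed form where applicable, otherwise by ODE integration; for each
    state the reported time is the first grid point t_k (k >= 1) with
    |Pi_i(t_k) - Pi_i(t_{k-1})| < epsilon.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pi0 = _check_pi0(pi0, space.n_states)
    times = np.linspace(0.0, T, n_grid)
    if space.n_regions == 2:
        sol = solve_stationary_2region(params, pi0)
        traj = sol.trajectory(times)
    else:
        traj = integrate_frequency_ode(params, space, pi0, T, n_grid)
    diffs = np.abs(np.diff(traj.values, axis=0))
    out: Dict[str, Optional[float]] = {}
    for k, label in enumerate(space.labels()):
        hits = np.nonzero(diffs[:, k] < epsilon)[0]
        out[label] = float(times[hits[0] + 1]) if hits.size else None
    return MixingTimes(
        times=out, epsilon=epsilon, dt=float(times[1] - times[0]), T=float(T)
    )
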