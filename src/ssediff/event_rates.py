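"""Per-state gain/loss event rates for GeoSSE and BiSSE.

For each range state ``i`` the instantaneous probability flux of gaining or
losing one species decomposes into four event classes:

* ``W`` — within-region speciation (gain only: speciation in region l by any
  species whose range contains l creates a new endemic of {l}; the parent is
  unchanged, so W- = 0);
* ``D`` — dispersal (an endemic-or-widespread range adds one region);
* ``B`` — between-region speciation (a widespread range splits into two
  disjoint daughter ranges covering the parent);
* ``E`` — local extinction (a range drops one region; an endemic species
  losing its last region goes globally extinct).

All quantities in this module are *rates* (events per unit time): the
per-Delta-t transition probabilities divided by Delta-t.  The same functions
serve the diffusion stepping, the exact jump-process simulator and the
large-population ODE limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state_space import (
    BiSSEParams,
    GeoSSEParams,
    RangeState,
    StateSpace,
)


@dataclass(frozen=True)
class RateComponents:
    """Gain (plus) and loss (minus) rate components for one focal state."""

    W_plus: float = 0.0
    D_plus: float = 0.0
    B_plus: float = 0.0
    E_plus: float = 0.0
    W_minus: float = 0.0
    D_minus: float = 0.0
    B_minus: float = 0.0
    E_minus: float = 0.0

    @property
    def plus_total(self) -> float:
        return self.W_plus + self.D_plus + self.B_plus + self.E_plus

    @property
    def minus_total(self) -> float:
        return self.W_minus + self.D_minus + self.B_minus + self.E_minus


def _check_counts(counts, space: StateSpace) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (space.n_states,):
        raise ValueError(
            f"counts must have shape ({space.n_states},), got {arr.shape}"
        )
    return arr


def gain_rate(
    counts, params: GeoSSEParams, state: RangeState, space: StateSpace
) -> RateComponents:
    """Rate components for gaining one species with range ``state``.

    ``counts`` is the per-state abundance vector in canonical state order.
    """
    n = _check_counts(counts, space)
    i = state
    space.index(i)  # raises if the state is foreign

    W = 0.0
    if len(i) == 1:
        (l,) = i.regions
        wl = params.w[l]
        for j in space.states:
            if l in j:
                W += n[space.index(j)] * wl

    D = 0.0
    if len(i) >= 2:
        for l in i:
            src = i.minus(l)
            nsrc = n[space.index(src)]
            D += nsrc * sum(params.d[(k, l)] for k in src)

    B = 0.0
    for j in space.states:
        if len(j) > len(i) and i.issubset(j):
            rest = tuple(r for r in j.regions if r not in i)
            B += n[space.index(j)] * params.b_rate(rest, i.regions)

    E = 0.0
    for j in space.states:
        if len(j) == len(i) + 1 and i.issubset(j):
            (l,) = (r for r in j.regions if r not in i)
            E += n[space.index(j)] * params.e[l]

    return RateComponents(W_plus=W, D_plus=D, B_plus=B, E_plus=E)


def loss_rate(
    counts, params: GeoSSEParams, state: RangeState, space: StateSpace
) -> RateComponents:
    """Rate components for losing one species with range ``state``."""
    n = _check_counts(counts, space)
    i = state
    ni = n[space.index(i)]

    # dispersal into any region not yet in the range moves the species to a
    # larger range; a full-range species cannot disperse anywhere new
    D = 0.0
    if len(i) < space.n_regions:
        outside = [l for l in space.regions if l not in i]
        D = ni * sum(params.d[(k, l)] for l in outside for k in i)

    # each ordered proper subset counted with factor 1/2 (left/right daughter
    # double-count), which collapses to one term per unordered split
    B = 0.0
    if len(i) >= 2:
        for left, right in space.splits(i):
            B += ni * params.b_rate(left.regions, right.regions)

    E = ni * sum(params.e[l] for l in i)

    return RateComponents(D_minus=D, B_minus=B, E_minus=E)


def per_capita_rates(
    freqs, params: GeoSSEParams, state: RangeState, space: StateSpace
):
    """Per-capita gain/loss rate totals at state frequencies ``freqs``.

    Structurally identical to :func:`gain_rate` / :func:`loss_rate` with
    counts replaced by frequencies; multiplying by the total species count N
    recovers the count-scale totals when ``freqs = counts / N``.
    """
    f = _check_counts(freqs, space)
    if np.any(f < -1e-12):
        raise ValueError("frequencies must be nonnegative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 (got {f.sum()!r})")
    plus = gain_rate(f, params, state, space).plus_total
    minus = loss_rate(f, params, state, space).minus_total
    return plus, minus


def flux_total(params: GeoSSEParams, state: RangeState, space: StateSpace) -> float:
    """Total rate-constant flux for a state: incoming minus outgoing.

    Each (source state, event) pair contributes one unit of its rate
    constant — equivalently, the gain/loss totals evaluated with every state
    count set to 1.  Used as ordering side conditions by the
    rate-from-frequency solver.
    """
    ones = np.ones(space.n_states)
    plus = gain_rate(ones, params, state, space).plus_total
    minus = loss_rate(ones, params, state, space).minus_total
    return plus - minus


@dataclass(frozen=True)
class BiSSEComponents:
    """BiSSE gain/loss components for one focal trait state."""

    S_plus: float = 0.0
    E_plus: float = 0.0
    Q_plus: float = 0.0
    S_minus: float = 0.0
    E_minus: float = 0.0
    Q_minus: float = 0.0

    @property
    def plus_total(self) -> float:
        return self.S_plus + self.E_plus + self.Q_plus

    @property
    def minus_total(self) -> float:
        return self.S_minus + self.E_minus + self.Q_minus


def bisse_components(counts, params: BiSSEParams, state: int) -> BiSSEComponents:
    """Gain/loss components for BiSSE trait state 1 or 2.

    Speciation copies the parent state to both daughters (no cladogenetic
    change), so speciation never removes a species from its state and
    extinction never adds one.
    """
    n = np.asarray(counts, dtype=float)
    if n.shape != (2,):
        raise ValueError("BiSSE counts must have shape (2,)")
    if state == 1:
        lam, mu = params.lambda1, params.mu1
        q_out, q_in = params.q12, params.q21
        ni, nother = n[0], n[1]
    elif state == 2:
        lam, mu = params.lambda2, params.mu2
        q_out, q_in = params.q21, params.q12
        ni, nother = n[1], n[0]
    else:
        raise ValueError(f"BiSSE state must be 1 or 2, got {state}")
    return BiSSEComponents(
        S_plus=lam * ni,
        Q_plus=q_in * nother,
        E_minus=mu * ni,
        Q_minus=q_out * ni,
    )


def rate_matrices(params: GeoSSEParams, space: StateSpace):
    """Linear-algebra form of the gain/loss totals.

    Both totals are linear in the count vector, so there are matrices with
    ``plus_total = Gp @ counts`` and ``minus_total = Gm @ counts`` (``Gm`` is
    diagonal: every loss term is proportional to the focal state's own
    count).  The count drift matrix ``A = Gp - Gm`` gives the linear count
    dynamics dN/dt = A N used by the projection-matrix stationary method, and
    per-capita drift is ``A @ freqs``.
    """
    S = space.n_states
    Gp = np.zeros((S, S))
    Gm = np.zeros((S, S))
    eye = np.eye(S)
    for col in range(S):
        for i, state in enumerate(space.states):
            Gp[i, col] = gain_rate(eye[col], params, state, space).plus_total
            Gm[i, col] = loss_rate(eye[col], params, state, space).minus_total
    return Gp, Gm


def count_drift_matrix(params: GeoSSEParams, space: StateSpace) -> np.ndarray:
    """Matrix A of the linear count dynamics dN/dt = A N."""
    Gp, Gm = rate_matrices(params, space)
    return Gp - Gm
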