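"""Infinitesimal drift/variance of count and frequency processes.

The count process N_i(t) for each state is approximated by a diffusion with
drift mu_i = P_i^+ - P_i^- and variance sigma_i^2 = P_i^+ + P_i^- (gain and
loss rate totals).  The frequency process Pi_i = N_i / N follows by the
multivariate Ito transform, under the model assumption that the per-state
count processes are driven independently (no cross-covariances).

The large-N frequency drift is the per-capita difference p+ - p-.  Note that
this as-printed limit neglects a -Pi_i * (net per-capita growth) term that
survives in the exact N -> infinity limit of the pre-limit drift whenever
total growth is nonzero; the growth-adjusted variant is available through
``adjust_for_growth=True`` and is the right object for convergence checks,
while the unadjusted form is the canonical drift used by the stationary
theory.  Both coincide at a stationary point, where every state's per-capita
gain and loss balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .event_rates import RateComponents, per_capita_rates
from .state_space import GeoSSEParams, StateSpace


class TotalExtinctionError(ValueError):
    """Raised when frequency diffusion parameters are requested at N = 0,
    where the frequency process is undefined."""


@dataclass(frozen=True)
class CountDiffusionParams:
    """Per-state drift (species / time) and variance (species^2 / time)."""

    mu: np.ndarray
    sigma2: np.ndarray


@dataclass(frozen=True)
class FrequencyDiffusionParams:
    """Per-state frequency drift and variance (per unit time)."""

    mu_pi: np.ndarray
    sigma2_pi: np.ndarray


def count_params(components: Sequence[RateComponents]) -> CountDiffusionParams:
    """Drift and variance of the count diffusion from rate components."""
    plus = np.array([c.plus_total for c in components])
    minus = np.array([c.minus_total for c in components])
    return CountDiffusionParams(mu=plus - minus, sigma2=plus + minus)


def ito_transform(mu: float, sigma2: float, g1: float, g2: float):
    """Ito's formula for Y = g(Z): drift picks up the curvature correction
    ``mu*g' + sigma^2*g''/2``; variance transforms as ``sigma^2 * g'^2``."""
    mu_y = mu * g1 + 0.5 * sigma2 * g2
    sigma2_y = sigma2 * g1 * g1
    return mu_y, sigma2_y


def multivariate_ito(partials, second_partials, mu, sigma2):
    """Multivariate Ito transform of X(n_1, ..., n_S).

    With independent component processes (zero cross-covariances),
    drift = sum_i dX/dn_i * mu_i + 1/2 sum_i d2X/dn_i^2 * sigma_i^2 and
    variance = sum_i (dX/dn_i)^2 * sigma_i^2.
    """
    p = np.asarray(partials, dtype=float)
    s = np.asarray(second_partials, dtype=float)
    m = np.asarray(mu, dtype=float)
    v = np.asarray(sigma2, dtype=float)
    if not (p.shape == s.shape == m.shape == v.shape):
        raise ValueError("partials, second_partials, mu, sigma2 must share a shape")
    mu_x = float(p @ m + 0.5 * (s @ v))
    sigma2_x = float((p * p) @ v)
    return mu_x, sigma2_x


def frequency_params(
    cparams: CountDiffusionParams, counts
) -> FrequencyDiffusionParams:
    """Drift/variance of the frequency process at the given counts.

    mu_Pi_i = (mu_i - sigma_i^2/N)/N + (Pi_i/N) * sum_j(-mu_j + sigma_j^2/N)
    sigma2_Pi_i = (sigma_i/N)^2 (1 - 2 Pi_i) + (Pi_i/N)^2 sum_j sigma_j^2
    """
    n = np.asarray(counts, dtype=float)
    N = n.sum()
    if N <= 0:
        raise TotalExtinctionError(
            "frequency diffusion parameters are undefined at total count 0"
        )
    pi = n / N
    mu, s2 = cparams.mu, cparams.sigma2
    correction = np.sum(-mu + s2 / N)
    mu_pi = (mu - s2 / N) / N + pi / N * correction
    sigma2_pi = (np.sqrt(s2) / N) ** 2 * (1 - 2 * pi) + (pi / N) ** 2 * s2.sum()
    return FrequencyDiffusionParams(mu_pi=mu_pi, sigma2_pi=sigma2_pi)


def large_N_frequency_drift(
    freqs,
    params: GeoSSEParams,
    space: StateSpace,
    adjust_for_growth: bool = False,
) -> np.ndarray:
    """Deterministic frequency drift in the large-population limit.

    The default returns the per-capita gain/loss difference p_i^+ - p_i^-
    per state (the drift the stationary theory is built on; the companion
    variance vanishes in the limit).  With ``adjust_for_growth=True`` the
    frequency-share correction -Pi_i * sum_j (p_j^+ - p_j^-) is subtracted,
    which is the exact limit of the finite-N frequency drift.
    """
    f = np.asarray(freqs, dtype=float)
    drift = np.empty(space.n_states)
    for k, state in enumerate(space.states):
        plus, minus = per_capita_rates(f, params, state, space)
        drift[k] = plus - minus
    if adjust_for_growth:
        drift = drift - f * drift.sum()
    return drift
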