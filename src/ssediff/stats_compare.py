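"""Statistical comparison of two simulation ensembles.

Implements the validation protocol used to decide whether diffusion-based
and jump-process (tree-equivalent) ensembles are statistically
indistinguishable state by state: Welch's unequal-variances t-test on the
terminal means, an F-test on the terminal variances, and the 95% confidence
interval for the variance ratio.  The two-sided F-test p-value convention is
2 * min(P(F <= f), P(F >= f)).  No multiple-testing correction is applied
across states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import stats

from .simulate import EnsembleSummary

_Z95 = 1.959963984540054


def _check_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"{name} needs at least 2 observations")
    return arr


def welch_test(sample_a, sample_b) -> Tuple[float, float, float]:
    """Two-sided Welch t-test; returns (statistic, dof, p)."""
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples are degenerate with unequal means")
    sa, sb = va / a.size, vb / b.size
    dof = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(dof), float(res.pvalue)


def f_variance_test(sample_a, sample_b) -> Tuple[float, float]:
    """Variance-ratio F-test; F = s2_a / s2_b with (n_a-1, n_b-1) dof."""
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValueError("denominator sample has zero variance")
    F = a.var(ddof=1) / vb
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return float(F), float(min(p, 1.0))


def variance_ratio_ci(
    sample_a, sample_b, level: float = 0.95
) -> Tuple[float, float, float]:
    """Variance ratio r = s2_a / s2_b with its equal-tailed CI
    (r / F_upper, r / F_lower) from the F distribution."""
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValueError("denominator sample has zero variance")
    r = a.var(ddof=1) / vb
    alpha = 1.0 - level
    dist = stats.f(a.size - 1, b.size - 1)
    lower = r / dist.ppf(1 - alpha / 2)
    upper = r / dist.ppf(alpha / 2)
    return float(r), float(lower), float(upper)


@dataclass
class StateComparison:
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    ci_a: Tuple[float, float]
    ci_b: Tuple[float, float]
    t_stat: float
    t_dof: float
    p_mean: float
    f_stat: float
    p_var: float
    r_var: float
    r_var_ci: Tuple[float, float]


@dataclass
class ComparisonReport:
    """Per-state ensemble comparison plus an overall mean-equality verdict."""

    states: Dict[str, StateComparison]
    alpha: float
    indistinguishable_means: bool

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "indistinguishable_means": self.indistinguishable_means,
            "states": {
                label: {
                    "mean_a": c.mean_a,
                    "mean_b": c.mean_b,
                    "var_a": c.var_a,
                    "var_b": c.var_b,
                    "ci_a": list(c.ci_a),
                    "ci_b": list(c.ci_b),
                    "p_mean": c.p_mean,
                    "p_var": c.p_var,
                    "r_var": c.r_var,
                    "r_var_ci": list(c.r_var_ci),
                }
                for label, c in self.states.items()
            },
        }


def _mean_ci(x: np.ndarray) -> Tuple[float, float]:
    half = _Z95 * np.sqrt(x.var(ddof=1) / x.size)
    return float(x.mean() - half), float(x.mean() + half)


def compare_ensembles(
    a: EnsembleSummary, b: EnsembleSummary, alpha: float = 0.05
) -> ComparisonReport:
    """Compare two ensembles state by state (a is typically the diffusion
    ensemble and b the jump-process reference)."""
    if a.labels != b.labels:
        raise ValueError("ensembles are defined over different state spaces")
    states: Dict[str, StateComparison] = {}
    all_means_ok = True
    for k, label in enumerate(a.labels):
        xa = a.terminal_values[:, k]
        xb = b.terminal_values[:, k]
        t, dof, p_mean = welch_test(xa, xb)
        try:
            F, p_var = f_variance_test(xa, xb)
            r, lo, hi = variance_ratio_ci(xa, xb)
        except ValueError:
            F = p_var = r = lo = hi = float("nan")
        states[label] = StateComparison(
            mean_a=float(xa.mean()),
            mean_b=float(xb.mean()),
            var_a=float(xa.var(ddof=1)),
            var_b=float(xb.var(ddof=1)),
            ci_a=_mean_ci(xa),
            ci_b=_mean_ci(xb),
            t_stat=t,
            t_dof=dof,
            p_mean=p_mean,
            f_stat=F,
            p_var=p_var,
            r_var=r,
            r_var_ci=(lo, hi),
        )
        all_means_ok = all_means_ok and p_mean > alpha
    return ComparisonReport(
        states=states, alpha=alpha, indistinguishable_means=all_means_ok
    )
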