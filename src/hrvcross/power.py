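"""A priori power for repeated-measures within-subject effects, and the
blinding-accuracy check.

The power model is the noncentral-F approximation used by G*Power's
"ANOVA: repeated measures, within factors" procedure: for total sample size
N split equally over ``groups`` groups, ``m`` repeated measurements with
pairwise correlation ``rho`` and nonsphericity ``epsilon``,

    lambda = f^2 * N * m * epsilon / (1 - rho)
    df1    = (m - 1) * epsilon
    df2    = (N - groups) * (m - 1) * epsilon

and power = P(F' > F_crit) with F' noncentral F(df1, df2, lambda). Because
groups are filled equally, the required *total* sample size is reported in
multiples of the number of groups.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerQuery", "achieved_power", "required_sample_size", "blinding_accuracy"]


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of the repeated-measures power calculation."""

    f: float = 0.15
    alpha: float = 0.05
    target_power: float = 0.90
    groups: int = 2
    measurements: int = 4
    rho: float = 0.8
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.measurements < 2:
            raise ValueError("need at least two repeated measurements")
        if self.groups < 1:
            raise ValueError("need at least one group")
        if self.f < 0:
            raise ValueError("effect size f must be non-negative")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")


def achieved_power(n_total: int, q: PowerQuery) -> float:
    """Power of the within-subject F test at total sample size ``n_total``."""
    if n_total <= q.groups:
        raise ValueError("total sample size must exceed the number of groups")
    m, eps = q.measurements, q.epsilon
    lam = q.f**2 * n_total * m * eps / (1.0 - q.rho)
    df1 = (m - 1) * eps
    df2 = (n_total - q.groups) * (m - 1) * eps
    f_crit = stats.f.ppf(1.0 - q.alpha, df1, df2)
    if lam == 0:  # scipy's ncf is numerically unreliable at zero noncentrality
        return float(q.alpha)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def required_sample_size(q: PowerQuery, n_max: int = 100_000) -> int:
    """Smallest total N (a multiple of ``groups``, equal allocation) whose
    power reaches ``q.target_power``."""
    if q.f == 0:
        raise ValueError("power never exceeds alpha when f = 0")
    n = q.groups * max(2, (q.groups + 2 + q.groups - 1) // q.groups)
    while n <= n_max:
        if achieved_power(n, q) >= q.target_power:
            return n
        n += q.groups
    raise ValueError(f"target power {q.target_power} not reachable below N={n_max}")


def blinding_accuracy(correct: int, total: int) -> dict:
    """Guessing accuracy of the blinding check with an exact binomial test.

    Returns ``{"accuracy_percent": 100*correct/total rounded to one decimal,
    "p_binomial": two-sided exact p vs. chance 0.5}``.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("correct must lie in [0, total]")
    test = stats.binomtest(correct, total, 0.5, alternative="two-sided")
    return {
        "accuracy_percent": round(100.0 * correct / total, 1),
        "p_binomial": float(test.pvalue),
        "correct": correct,
        "total": total,
    }
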