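"""One-way ANOVA with Tukey HSD, and Pearson correlation with Fisher-z CI.

These are the textbook procedures the bootstrap pipeline reports alongside
its own inference: per-isolate all-pairs mean comparisons across the three
arms (studentized-range adjusted, Tukey-Kramer form for unequal group
sizes), and product-moment correlations on isolate-level means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientReplicationError, UndefinedStatisticError

__all__ = [
    "PairComparison",
    "TukeyResult",
    "CorrelationResult",
    "anova_tukey",
    "pearson_ci",
]


@dataclass(frozen=True)
class PairComparison:
    group_a: str
    group_b: str
    diff: float  # mean(group_b) - mean(group_a)
    se: float
    q: float
    p_adj: float


@dataclass(frozen=True)
class TukeyResult:
    pairs: tuple[PairComparison, ...]
    k_groups: int
    df_error: int
    mse: float

    def pair(self, a: str, b: str) -> PairComparison:
        for p in self.pairs:
            if {p.group_a, p.group_b} == {a, b}:
                return p
        raise KeyError(f"no pair ({a}, {b}) in result")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    alpha: float


def anova_tukey(groups: dict[str, "np.typing.ArrayLike"]) -> TukeyResult:
    """Tukey HSD over labeled groups, assuming homoscedasticity.

    The pooled mean squared error has N - k degrees of freedom. For each
    pair, q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) and the
    adjusted p is the upper tail of the studentized-range distribution
    with parameters (k, N - k). With zero pooled variance and unequal
    means, p is reported at the machine floor with a warning.
    """
    if len(groups) < 2:
        raise InsufficientReplicationError("need at least 2 groups")
    labels = list(groups)
    data = {lab: np.asarray(groups[lab], dtype=float) for lab in labels}
    for lab, arr in data.items():
        if arr.ndim != 1 or arr.size < 2:
            raise InsufficientReplicationError(
                f"group {lab!r} needs >= 2 values, got {arr.size}"
            )
    k = len(labels)
    n_total = sum(arr.size for arr in data.values())
    df_error = n_total - k
    mse = sum((arr.size - 1) * arr.var(ddof=1) for arr in data.values()) / df_error

    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            xa, xb = data[a], data[b]
            diff = float(xb.mean() - xa.mean())
            se = float(np.sqrt(mse / 2.0 * (1.0 / xa.size + 1.0 / xb.size)))
            if se == 0.0:
                if diff == 0.0:
                    q, p = 0.0, 1.0
                else:
                    warnings.warn(
                        f"zero pooled variance with unequal means for pair ({a}, {b}); "
                        "adjusted p reported at the machine floor",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    q, p = float("inf"), float(np.finfo(float).tiny)
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_error))
            pairs.append(PairComparison(a, b, diff, se, q, min(max(p, 0.0), 1.0)))
    return TukeyResult(tuple(pairs), k, df_error, float(mse))


def pearson_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson r with two-sided t-test p and Fisher-z confidence interval.

    r is the product-moment correlation; p comes from
    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom; the CI is
    atanh(r) +/- z_{1-alpha/2}/sqrt(n-3), back-transformed through tanh.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise UndefinedStatisticError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise InsufficientReplicationError(f"need n >= 4 points, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
        lo = hi = r
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
        zcrit = float(stats.norm.ppf(1.0 - alpha / 2.0))
        z = np.arctanh(r)
        half = zcrit / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return CorrelationResult(r=r, p=p, ci_low=lo, ci_high=hi, n=n, alpha=alpha)
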