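"""Unstandardized effect sizes with non-parametric bootstrap inference.

The effect size (ES) of a treatment on a response is the difference of
group means, treated minus control, in the response's native units
(negative = reduction). Uncertainty is quantified by the percentile
bootstrap: replicates are resampled with replacement within each arm
independently (the replicate is the only exchangeable unit of the design),
and the 95% interval is read off the empirical quantiles of the resampled
statistic. The gradual-vs-abrupt contrast resamples both treated arms and
reports a two-sided Monte-Carlo p-value for delta = ES_abrupt - ES_gradual
with the standard +1 correction, so p is never exactly zero and is bounded
below by 2/(n_boot+1).

The contrast p-value is studentized (bootstrap-t): the raw percentile
distribution of the resampled difference understates its own spread at the
5-replicates-per-arm scale of this design and rejects a true null more
than twice too often, whereas pivoting on t* = (D* - delta)/SE* restores
the nominal level (doubled tail proportions are then taken on t* against
t_obs = delta/SE). The CI for delta remains the percentile interval.

No multiplicity correction is applied across isolates; downstream reports
flag this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientReplicationError

__all__ = ["EffectSize", "ESComparison", "effect_size", "bootstrap_ci", "compare_es"]

DEFAULT_N_BOOT = 9999


@dataclass(frozen=True)
class EffectSize:
    """Point estimate and percentile-bootstrap CI of mean(treated) - mean(control)."""

    point: float
    ci_low: float
    ci_high: float
    n_treated: int
    n_control: int
    n_boot: int
    alpha: float

    def excludes_zero(self) -> bool:
        """True when the CI lies strictly on one side of zero."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass(frozen=True)
class ESComparison:
    """Bootstrap contrast between the two treated arms.

    ``delta`` is ES_abrupt - ES_gradual (the control means cancel, so this
    equals mean(abrupt) - mean(gradual)); ``p_boot`` is the doubled tail
    proportion of the studentized bootstrap null distribution, capped at 1.
    """

    delta: float
    ci_low: float
    ci_high: float
    p_boot: float
    n_boot: int
    alpha: float


def _check_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InsufficientReplicationError(
            f"group {name!r} needs >= 2 replicate values, got {arr.size}"
        )
    return arr


def effect_size(treated, control) -> float:
    """mean(treated) - mean(control), in the response's units."""
    t = _check_group(treated, "treated")
    c = _check_group(control, "control")
    return float(t.mean() - c.mean())


def bootstrap_ci(
    treated,
    control,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = 0.05,
    seed: int | None = None,
) -> EffectSize:
    """Percentile-bootstrap CI for the mean difference.

    Each bootstrap iteration resamples both arms with replacement,
    independently; the CI is the (alpha/2, 1-alpha/2) quantile pair of the
    resampled mean differences.
    """
    t = _check_group(treated, "treated")
    c = _check_group(control, "control")
    if n_boot < 1000:
        raise InsufficientReplicationError(f"n_boot must be >= 1000, got {n_boot}")
    rng = np.random.default_rng(seed)
    t_star = t[rng.integers(0, t.size, (n_boot, t.size))].mean(axis=1)
    c_star = c[rng.integers(0, c.size, (n_boot, c.size))].mean(axis=1)
    diffs = t_star - c_star
    lo, hi = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return EffectSize(
        point=float(t.mean() - c.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_treated=t.size,
        n_control=c.size,
        n_boot=n_boot,
        alpha=alpha,
    )


def compare_es(
    gradual,
    abrupt,
    control,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ESComparison:
    """Bootstrap contrast delta = ES_abrupt - ES_gradual.

    All three arms are conceptually resampled per iteration; because the
    control mean enters both effect sizes identically it cancels from every
    bootstrap draw, so only the treated arms are actually resampled.

    The CI is the percentile interval of the resampled difference D*. The
    p-value is the doubled tail proportion of the studentized null
    distribution t* = (D* - delta)/SE* relative to t_obs = delta/SE (+1
    corrected), where SE collects both arms' resampled standard errors of
    the mean; draws with zero resampled variance in both arms carry no
    pivot information and are dropped from the p-value count.

    When the treated arms have equal size, resample-index pairs are laid
    out in a mirrored scheme (each index pair is used once per role
    ordering, plus one shared-index draw when ``n_boot`` is odd). Every
    draw remains an ordinary bootstrap draw, and the layout makes the
    procedure exactly antisymmetric: swapping the gradual and abrupt
    arguments negates delta, mirrors the CI, and leaves p_boot unchanged.
    """
    g = _check_group(gradual, "gradual")
    a = _check_group(abrupt, "abrupt")
    _check_group(control, "control")
    rng = np.random.default_rng(seed)

    if g.size == a.size:
        n = g.size
        half = n_boot // 2
        u = rng.integers(0, n, (half, n))
        v = rng.integers(0, n, (half, n))
        if n_boot % 2:
            w = rng.integers(0, n, (1, n))
            g_idx = np.concatenate([u, v, w])
            a_idx = np.concatenate([v, u, w])
        else:
            g_idx = np.concatenate([u, v])
            a_idx = np.concatenate([v, u])
    else:
        g_idx = rng.integers(0, g.size, (n_boot, g.size))
        a_idx = rng.integers(0, a.size, (n_boot, a.size))
    g_star = g[g_idx]
    a_star = a[a_idx]
    diffs = a_star.mean(axis=1) - g_star.mean(axis=1)

    delta = float(a.mean() - g.mean())
    lo = float(np.quantile(diffs, alpha / 2.0))
    # upper endpoint via the negated sample so the interval mirrors exactly
    # under arm swap (interpolation is not otherwise float-symmetric)
    hi = float(-np.quantile(-diffs, alpha / 2.0))

    se_obs = math.sqrt(g.var(ddof=1) / g.size + a.var(ddof=1) / a.size)
    if se_obs == 0.0:
        p = 1.0 if delta == 0.0 else 2.0 / (n_boot + 1)
    else:
        t_obs = delta / se_obs
        se_star = np.sqrt(
            g_star.var(axis=1, ddof=1) / g.size + a_star.var(axis=1, ddof=1) / a.size
        )
        valid = se_star > 0.0
        t_star = (diffs[valid] - delta) / se_star[valid]
        m = int(valid.sum())
        n_le = int(np.count_nonzero(t_star <= t_obs))
        n_ge = int(np.count_nonzero(t_star >= t_obs))
        p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (m + 1))
    return ESComparison(
        delta=delta,
        ci_low=lo,
        ci_high=hi,
        p_boot=float(p),
        n_boot=n_boot,
        alpha=alpha,
    )
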