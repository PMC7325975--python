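"""Reaction-pattern and stress-strategy classification of isolates.

Reaction patterns formalize the four qualitative biomass outcomes — no
significant effect, equal reduction under both deliveries, stronger
reduction under gradual delivery, stronger reduction under abrupt delivery
— as an ordered decision rule over the bootstrap effect sizes and the
gradual-vs-abrupt contrast, keeping the whole call inside one inferential
family (the bootstrap; Tukey results are reported alongside but do not
drive the call):

1. neither arm's ES CI excludes zero            -> no_effect
2. contrast not significant (p_boot >= alpha)   -> uniform_reduction
3. ES_gradual below ES_abrupt                   -> gradual_worse
4. otherwise                                    -> abrupt_worse

Strategies place each isolate x treatment in a quadrant of the joint
growth/accumulation response: the growth axis splits the biomass ES at the
panel median, the accumulation axis splits the copper ES at the panel
median (ties go to the lower half), giving grow-and-accumulate (a),
grow-and-exclude (b), inhibited-and-accumulate (c), inhibited-and-exclude
(d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .effects import EffectSize, ESComparison
from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "PATTERN_LABELS",
    "STRATEGY_LABELS",
    "PatternCall",
    "StrategyCall",
    "classify_pattern",
    "classify_strategy",
    "panel_medians",
]

PATTERN_LABELS = ("no_effect", "uniform_reduction", "gradual_worse", "abrupt_worse")
STRATEGY_LABELS = (
    "a_grow_accumulate",
    "b_grow_exclude",
    "c_inhibited_accumulate",
    "d_inhibited_exclude",
)


@dataclass(frozen=True)
class PatternCall:
    label: str
    es_gradual: EffectSize
    es_abrupt: EffectSize
    contrast: ESComparison
    alpha: float


@dataclass(frozen=True)
class StrategyCall:
    label: str
    growth_median: float
    accumulation_median: float


def classify_pattern(
    es_g: EffectSize,
    es_a: EffectSize,
    contrast: ESComparison,
    alpha: float = 0.05,
) -> PatternCall:
    """Apply the four-rule reaction-pattern decision, in order.

    All three inputs must have been computed at the same ``alpha`` so the
    CI-excludes-zero checks and the contrast test share one level.
    """
    if not (es_g.alpha == es_a.alpha == contrast.alpha == alpha):
        raise ConfigurationError(
            "effect sizes, contrast and classification must share one alpha "
            f"(got {es_g.alpha}, {es_a.alpha}, {contrast.alpha}, {alpha})"
        )
    if not (es_g.excludes_zero() or es_a.excludes_zero()):
        label = "no_effect"
    elif contrast.p_boot >= alpha:
        label = "uniform_reduction"
    elif es_g.point < es_a.point:
        label = "gradual_worse"
    else:
        label = "abrupt_worse"
    return PatternCall(label, es_g, es_a, contrast, alpha)


def panel_medians(
    es_biomass: Sequence[EffectSize], es_cu: Sequence[EffectSize]
) -> tuple[float, float]:
    """Panel medians of the biomass and copper ES point estimates.

    Computed across all isolates for one treatment arm; these define the
    quadrant split for :func:`classify_strategy`.
    """
    if len(es_biomass) == 0 or len(es_cu) == 0:
        raise InvalidParameterError("panel medians need a non-empty panel")
    mb = float(np.median([e.point for e in es_biomass]))
    mc = float(np.median([e.point for e in es_cu]))
    return mb, mc


def classify_strategy(
    es_biomass: EffectSize,
    es_cu: EffectSize,
    medians: tuple[float, float],
) -> StrategyCall:
    """Quadrant label for one isolate under one treatment.

    Growth is "high" when the biomass ES is strictly above the panel
    median (values at the median tie-break to the lower half), and
    likewise for accumulation with the copper ES.
    """
    growth_median, accum_median = medians
    grow_high = es_biomass.point > growth_median
    accum_high = es_cu.point > accum_median
    if grow_high and accum_high:
        label = "a_grow_accumulate"
    elif grow_high:
        label = "b_grow_exclude"
    elif accum_high:
        label = "c_inhibited_accumulate"
    else:
        label = "d_inhibited_exclude"
    return StrategyCall(label, float(growth_median), float(accum_median))
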