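"""Effect sizes: differences in abnormality proportions with Newcombe CIs.

Odds ratios are unusable for rare events (zero cells give infinite
estimates), so effects are reported as differences in abnormality
proportions.  Interval estimation uses Newcombe's method 10: square-and-add
the distances from each proportion to its Wilson score bounds (no
continuity correction), recommended for highly unbalanced designs.
"""

from __future__ import annotations

import math

from statsmodels.stats.proportion import proportion_confint

from .tables import EffectEstimate, SexStratifiedCounts, ValidationError

__all__ = [
    "wilson_ci",
    "newcombe_diff_ci",
    "sex_averaged_effect",
    "ko_sex_difference",
]


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a single proportion, no continuity correction."""
    if n < 1:
        raise ValidationError("wilson_ci requires n >= 1")
    if not 0 <= k <= n:
        raise ValidationError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def newcombe_diff_ci(k1: int, n1: int, k2: int, n2: int,
                     level: float = 0.95) -> EffectEstimate:
    """Newcombe method-10 CI for the difference p1 - p2.

    With per-group Wilson bounds (l1, u1) and (l2, u2):

        lower = d - sqrt((p1 - l1)^2 + (u2 - p2)^2)
        upper = d + sqrt((u1 - p1)^2 + (p2 - l2)^2)
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("both groups must be non-empty")
    p1, p2 = k1 / n1, k2 / n2
    l1, u1 = wilson_ci(k1, n1, level)
    l2, u2 = wilson_ci(k2, n2, level)
    d = p1 - p2
    lower = d - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    upper = d + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return EffectEstimate(estimate=d, lower=max(lower, -1.0),
                          upper=min(upper, 1.0), level=level)


def sex_averaged_effect(d: SexStratifiedCounts,
                        level: float = 0.95) -> EffectEstimate:
    """Sex-averaged knockout effect with a conservative pooled interval.

    The estimate is the mean of the two per-sex KO-minus-WT differences; the
    interval takes the minimum of the two lower bounds and the maximum of
    the two upper bounds, so it contains both per-sex intervals.  If one sex
    is absent the present sex's interval is returned.
    """
    per_sex = []
    for s in (d.male, d.female):
        if s.total_a >= 1 and s.total_b >= 1:
            per_sex.append(newcombe_diff_ci(s.events_a, s.total_a,
                                            s.events_b, s.total_b, level))
    if not per_sex:
        raise ValidationError("no sex with both wild-type and knockout animals")
    if len(per_sex) == 1:
        return per_sex[0]
    m, f = per_sex
    return EffectEstimate(
        estimate=0.5 * (m.estimate + f.estimate),
        lower=min(m.lower, f.lower),
        upper=max(m.upper, f.upper),
        level=level,
    )


def ko_sex_difference(d: SexStratifiedCounts,
                      level: float = 0.95) -> EffectEstimate:
    """Male-minus-female difference in abnormality rate among knockouts."""
    if d.male.total_a < 1 or d.female.total_a < 1:
        raise ValidationError("knockouts of both sexes required")
    return newcombe_diff_ci(d.male.events_a, d.male.total_a,
                            d.female.events_a, d.female.total_a, level)
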