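"""Minimum attainable P-values (alpha star) and attainability filtering.

Discrete tests on small tables often cannot reach the significance level at
all: given the fixed margins, even the most extreme attainable outcome has a
P-value above the threshold.  Filtering such hypotheses out BEFORE testing
shrinks the multiple-testing family without peeking at outcomes — alpha star
depends only on the margins, so the filter does not bias downstream FDR
control.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .exact import _convolved_ko_events, _tail_p
from .firth import lr_ko_from_counts
from .tables import SexStratifiedCounts, ValidationError

__all__ = [
    "AlphaStarRecord",
    "mh_alpha_star",
    "lrko_alpha_star",
    "apply_filters",
    "lrko_alpha_star_grid",
]


@dataclass(frozen=True)
class AlphaStarRecord:
    dataset_id: str
    alpha_star_stage1: float
    alpha_star_stage2: float
    pass_stage1_filter: bool = False
    pass_stage2_filter: bool = False


def mh_alpha_star(d: SexStratifiedCounts, mid: bool = True) -> float:
    """Smallest attainable (mid-)P of the exact stratified MH test.

    The minimum over all tables with the observed margins; for the one-sided
    upper-tail statistic that is attained at the largest attainable total
    knockout-event count, but the minimum is taken over the whole support.
    """
    lo, pmf = _convolved_ko_events(d)
    if len(pmf) == 1:
        return 0.5 if mid else 1.0
    return min(_tail_p(pmf, i, mid=mid) for i in range(len(pmf)))


@lru_cache(maxsize=50_000)
def _lrko_alpha_star_cached(n_male: int, n_female: int, total_abnormal: int,
                            mode: str) -> float:
    if n_male <= 0 or n_female <= 0:
        raise ValidationError("alpha star needs knockouts of both sexes")
    if total_abnormal > n_male + n_female:
        raise ValidationError("more abnormalities than knockout animals")
    lo = max(0, total_abnormal - n_female)
    hi = min(total_abnormal, n_male)
    if lo == hi:
        return 1.0  # single attainable allocation: no sex signal possible
    # enumerate every allocation rather than assuming the extreme split is
    # optimal; guards against unequal n per sex
    best = 1.0
    for a in range(lo, hi + 1):
        p = lr_ko_from_counts(n_male, n_female, a, total_abnormal - a,
                              mode=mode).p_value
        best = min(best, p)
    return best


def lrko_alpha_star(n_male: int, n_female: int, total_abnormal_ko: int,
                    *, mode: str = "full-penalty") -> float:
    """Smallest attainable LR_KO p for a fixed knockout abnormality total.

    Enumerates every allocation of ``total_abnormal_ko`` events between the
    sexes (respecting capacities) and minimizes the penalized-LRT p-value.
    With zero events only one allocation exists and the result is 1.
    """
    return _lrko_alpha_star_cached(int(n_male), int(n_female),
                                   int(total_abnormal_ko), mode)


def lrko_alpha_star_grid(n_male: int, n_female: int,
                         *, mode: str = "full-penalty"):
    """Alpha-star for every abnormality total, as a table of dicts."""
    return [
        {
            "penetrance_pct": round(100.0 * k / (n_male + n_female) * 2, 1)
            if n_male == n_female else float("nan"),
            "n_per_sex": n_male if n_male == n_female else (n_male, n_female),
            "abnormalities": k,
            "alpha_star": lrko_alpha_star(n_male, n_female, k, mode=mode),
        }
        for k in range(0, max(n_male, n_female) + 1)
    ]


def apply_filters(records: list[AlphaStarRecord], stage1_threshold: float = 0.05,
                  stage2_threshold: float = 0.05) -> list[AlphaStarRecord]:
    """Mark which hypotheses can ever reach significance at each stage.

    Stage-1 survivors have alpha_star_stage1 below the stage-1 threshold;
    stage-2 candidates must additionally clear the stage-2 threshold.  The
    decision consults margins only, never observed p-values.
    """
    if not (0 < stage1_threshold <= 1) or not (0 < stage2_threshold <= 1):
        raise ValidationError("thresholds must lie in (0, 1]")
    out = []
    for r in records:
        s1 = stage1_threshold >= 1.0 or r.alpha_star_stage1 < stage1_threshold
        s2 = s1 and (stage2_threshold >= 1.0
                     or r.alpha_star_stage2 < stage2_threshold)
        out.append(AlphaStarRecord(r.dataset_id, r.alpha_star_stage1,
                                   r.alpha_star_stage2, s1, s2))
    return out
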