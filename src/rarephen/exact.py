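"""Exact conditional tests for sex-stratified 2x2 tables, with mid-P variants.

All tests condition on the table margins, so the null law of the test
statistic is (a convolution of) central hypergeometric distributions.  On
such discrete supports the standard tail P-value is conservative; the mid-P
variant subtracts half the point probability of the observed outcome:

    p_mid = P(T beyond observed) + 1/2 P(T = observed).

Stage-1 tests are one-sided toward more abnormalities in knockouts, the safe
direction when screening rare traits for an increase in "abnormal"; the
per-sex Fisher test also offers a two-sided option.  Degenerate conditional
laws (a single attainable outcome) return p = 1 (standard) / 0.5 (mid),
uniformly; the attainability filter removes such data sets upstream.

Probabilities are computed in log space (log-gamma arithmetic) and tails are
accumulated from the smaller side.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .tables import SexStratifiedCounts, TestResult, TwoByTwo

__all__ = [
    "fisher_one_sided",
    "fe_stage1",
    "mh_exact_mid",
    "zelen_mid",
    "fe_ko",
]

# relative tolerance for probability ties in two-sided point-probability tails
TIE_EPS = 1e-10


@lru_cache(maxsize=200_000)
def _hypergeom_pmf(n_a: int, n_b: int, m: int) -> tuple[int, tuple[float, ...]]:
    """PMF of the knockout-event count T given margins.

    T counts events in group a when ``m`` total events are distributed over
    ``n_a + n_b`` exchangeable animals.  Returns (support start, pmf).
    """
    lo = max(0, m - n_b)
    hi = min(m, n_a)
    ks = np.arange(lo, hi + 1)
    logw = (
        gammaln(n_a + 1) - gammaln(ks + 1) - gammaln(n_a - ks + 1)
        + gammaln(n_b + 1) - gammaln(m - ks + 1) - gammaln(n_b - (m - ks) + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return lo, tuple(w)


def _tail_p(pmf: np.ndarray, idx_obs: int, *, mid: bool) -> float:
    """One-sided upper-tail p accumulated from the extreme (smaller) side."""
    upper = float(np.sum(pmf[:idx_obs:-1])) if idx_obs < len(pmf) - 1 else 0.0
    point = float(pmf[idx_obs])
    p = upper + (0.5 * point if mid else point)
    return min(max(p, np.nextafter(0, 1)), 1.0)


def _point_prob_two_sided(pmf: np.ndarray, idx_obs: int, *, mid: bool) -> float:
    """Two-sided p by the point-probability method with tie tolerance."""
    p_obs = float(pmf[idx_obs])
    order = np.argsort(pmf)  # accumulate from the smallest probabilities
    keep = pmf[order] <= p_obs * (1.0 + TIE_EPS)
    p = float(np.sum(pmf[order][keep]))
    if mid:
        p -= 0.5 * p_obs
    return min(max(p, np.nextafter(0, 1)), 1.0)


def fisher_one_sided(t: TwoByTwo, mid: bool = False, *,
                     two_sided: bool = False) -> TestResult:
    """Fisher's exact test that the knockout (group a) rate exceeds wild-type.

    Conditional on margins, T = events_a is hypergeometric; the standard p is
    P(T >= observed), the mid-P replaces the observed atom by half of it.
    ``two_sided=True`` switches to the point-probability two-sided tail.
    """
    lo, pmf_t = _hypergeom_pmf(t.total_a, t.total_b, t.total_events)
    pmf = np.asarray(pmf_t)
    label = ("FE_mid" if mid else "FE") + ("_2s" if two_sided else "")
    if len(pmf) == 1:
        return TestResult(method=label, p_value=0.5 if mid else 1.0)
    idx = t.events_a - lo
    if two_sided:
        p = _point_prob_two_sided(pmf, idx, mid=mid)
    else:
        p = _tail_p(pmf, idx, mid=mid)
    return TestResult(method=label, p_value=p)


def fe_stage1(d: SexStratifiedCounts, mid: bool = False, *,
              two_sided: bool = False) -> TestResult:
    """Per-sex Fisher tests combined Bonferroni-style: 2 x min(p_M, p_F).

    The doubling accounts for testing each sex separately; the result is
    capped at 1.  If one sex is absent the present sex's p is returned
    unmultiplied, with a warning.
    """
    label = "FE_mid" if mid else "FE"
    present = [s for s in (d.male, d.female) if s.total > 0]
    if len(present) == 1:
        r = fisher_one_sided(present[0], mid=mid, two_sided=two_sided)
        return TestResult(method=label, p_value=r.p_value,
                          warnings=("single-sex input: p not doubled",))
    p_m = fisher_one_sided(d.male, mid=mid, two_sided=two_sided).p_value
    p_f = fisher_one_sided(d.female, mid=mid, two_sided=two_sided).p_value
    return TestResult(method=label, p_value=min(1.0, 2.0 * min(p_m, p_f)))


def _convolved_ko_events(d: SexStratifiedCounts):
    """Null law of total knockout events across the two sex strata."""
    lo_m, pmf_m = _hypergeom_pmf(d.male.total_a, d.male.total_b,
                                 d.male.total_events)
    lo_f, pmf_f = _hypergeom_pmf(d.female.total_a, d.female.total_b,
                                 d.female.total_events)
    pmf = np.convolve(np.asarray(pmf_m), np.asarray(pmf_f))
    pmf /= pmf.sum()
    return lo_m + lo_f, pmf


def mh_exact_mid(d: SexStratifiedCounts, mid: bool = True) -> TestResult:
    """Exact one-sided stratified Mantel-Haenszel test, mid-P by default.

    Conditional on all margins, T = total knockout events across the sex
    strata follows the convolution of the two central hypergeometric laws;
    the alternative is more events in knockouts.
    """
    label = "MH_mid" if mid else "MH"
    lo, pmf = _convolved_ko_events(d)
    if len(pmf) == 1:
        return TestResult(method=label, p_value=0.5 if mid else 1.0)
    t_obs = d.male.events_a + d.female.events_a
    p = _tail_p(pmf, t_obs - lo, mid=mid)
    return TestResult(method=label, p_value=p)


def zelen_mid(d: SexStratifiedCounts, mid: bool = True) -> TestResult:
    """Zelen's exact test of odds-ratio homogeneity across the sexes.

    Conditional on all margins AND on T = total knockout events, the male
    knockout-event count A1 has law f(a1) proportional to the product of the
    two per-stratum hypergeometric weights.  The two-sided p sums f over
    outcomes no more probable than the observed one (relative tie tolerance
    ``TIE_EPS``); the mid variant subtracts half the observed atom.  A
    single-point support gives p = 1 exactly.
    """
    label = "Zelen"
    lo_m, pmf_m = _hypergeom_pmf(d.male.total_a, d.male.total_b,
                                 d.male.total_events)
    lo_f, pmf_f = _hypergeom_pmf(d.female.total_a, d.female.total_b,
                                 d.female.total_events)
    t = d.male.events_a + d.female.events_a
    if t == 0:
        return TestResult(method=label, p_value=1.0)
    pmf_m = np.asarray(pmf_m)
    pmf_f = np.asarray(pmf_f)
    hi_m, hi_f = lo_m + len(pmf_m) - 1, lo_f + len(pmf_f) - 1
    a1_lo = max(lo_m, t - hi_f)
    a1_hi = min(hi_m, t - lo_f)
    a1s = np.arange(a1_lo, a1_hi + 1)
    f = pmf_m[a1s - lo_m] * pmf_f[(t - a1s) - lo_f]
    total = f.sum()
    if len(f) == 1 or total <= 0:
        return TestResult(method=label, p_value=1.0)
    f = f / total
    p = _point_prob_two_sided(f, int(d.male.events_a - a1_lo), mid=mid)
    return TestResult(method=label, p_value=p)


def fe_ko(d: SexStratifiedCounts, mid: bool = True) -> TestResult:
    """Two-sided (mid-)P Fisher test comparing sexes within knockouts only.

    The knockout 2x2 is sex x outcome; conditioning on its margins, the male
    knockout-event count is hypergeometric and the two-sided tail is the
    point-probability sum.
    """
    label = "FE_KO"
    ko = d.knockout_table()
    lo, pmf_t = _hypergeom_pmf(ko.total_a, ko.total_b, ko.total_events)
    pmf = np.asarray(pmf_t)
    if len(pmf) == 1:
        # single attainable outcome: no evidence either way (matches Zelen)
        return TestResult(method=label, p_value=1.0)
    p = _point_prob_two_sided(pmf, ko.events_a - lo, mid=mid)
    return TestResult(method=label, p_value=p)
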