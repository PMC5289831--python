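"""Shared fixtures and independent brute-force oracles.

The oracles enumerate every pair of 2x2 tables compatible with the observed
margins and accumulate exact probabilities from binomial coefficients; they
share no code with the implementations they check.
"""

from __future__ import annotations

from math import comb

import pytest

from rarephen.tables import SexStratifiedCounts, TwoByTwo


def hyper_point(n_a: int, n_b: int, m: int, a: int) -> float:
    """P(a events in group a | margins), by direct binomial coefficients."""
    if a < max(0, m - n_b) or a > min(m, n_a):
        return 0.0
    return comb(n_a, a) * comb(n_b, m - a) / comb(n_a + n_b, m)


def hyper_support(n_a: int, n_b: int, m: int) -> range:
    return range(max(0, m - n_b), min(m, n_a) + 1)


def oracle_fisher_one_sided(t: TwoByTwo, mid: bool) -> float:
    m = t.total_events
    sup = list(hyper_support(t.total_a, t.total_b, m))
    if len(sup) == 1:
        return 0.5 if mid else 1.0
    p = 0.0
    for a in sup:
        w = hyper_point(t.total_a, t.total_b, m, a)
        if a > t.events_a:
            p += w
        elif a == t.events_a:
            p += 0.5 * w if mid else w
    return p


def oracle_mh(d: SexStratifiedCounts, mid: bool) -> float:
    """Enumerate all pairs of tables with the observed margins."""
    sup_m = list(hyper_support(d.male.total_a, d.male.total_b,
                               d.male.total_events))
    sup_f = list(hyper_support(d.female.total_a, d.female.total_b,
                               d.female.total_events))
    if len(sup_m) * len(sup_f) == 1:
        return 0.5 if mid else 1.0
    t_obs = d.male.events_a + d.female.events_a
    p = 0.0
    for am in sup_m:
        wm = hyper_point(d.male.total_a, d.male.total_b,
                         d.male.total_events, am)
        for af in sup_f:
            wf = hyper_point(d.female.total_a, d.female.total_b,
                             d.female.total_events, af)
            t = am + af
            if t > t_obs:
                p += wm * wf
            elif t == t_obs:
                p += (0.5 if mid else 1.0) * wm * wf
    return p


def oracle_zelen(d: SexStratifiedCounts, mid: bool, eps: float = 1e-10) -> float:
    t = d.male.events_a + d.female.events_a
    if t == 0:
        return 1.0
    weights = {}
    for am in hyper_support(d.male.total_a, d.male.total_b,
                            d.male.total_events):
        af = t - am
        wf = hyper_point(d.female.total_a, d.female.total_b,
                         d.female.total_events, af)
        wm = hyper_point(d.male.total_a, d.male.total_b,
                         d.male.total_events, am)
        if wm * wf > 0:
            weights[am] = wm * wf
    total = sum(weights.values())
    if len(weights) <= 1 or total == 0:
        return 1.0
    f_obs = weights[d.male.events_a] / total
    p = sum(w / total for w in weights.values()
            if w / total <= f_obs * (1 + eps))
    if mid:
        p -= 0.5 * f_obs
    return p


def oracle_fe_ko(d: SexStratifiedCounts, mid: bool, eps: float = 1e-10) -> float:
    ko = d.knockout_table()
    sup = list(hyper_support(ko.total_a, ko.total_b, ko.total_events))
    if len(sup) == 1:
        return 1.0
    probs = {a: hyper_point(ko.total_a, ko.total_b, ko.total_events, a)
             for a in sup}
    p_obs = probs[ko.events_a]
    p = sum(w for w in probs.values() if w <= p_obs * (1 + eps))
    if mid:
        p -= 0.5 * p_obs
    return p


@pytest.fixture
def small_dataset() -> SexStratifiedCounts:
    """Per sex: WT 1/20 abnormal, KO 4/7 — informative but tiny."""
    return SexStratifiedCounts(
        male=TwoByTwo(4, 7, 1, 20),
        female=TwoByTwo(4, 7, 1, 20),
        line_id="lineA", zygosity="hom", trait_id="trait1",
    )
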