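"""Exact conditional tests checked against brute-force enumeration oracles
and their defining discrete-distribution properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (oracle_fe_ko, oracle_fisher_one_sided, oracle_mh,
                      oracle_zelen)
from rarephen.exact import (_hypergeom_pmf, fe_ko, fe_stage1,
                            fisher_one_sided, mh_exact_mid, zelen_mid)
from rarephen.tables import SexStratifiedCounts, TwoByTwo, ValidationError

# strategies for valid small tables / stratified tables
def twobytwo(max_n=12):
    return st.tuples(st.integers(0, max_n), st.integers(0, max_n),
                     st.integers(0, max_n), st.integers(0, max_n)).map(
        lambda t: TwoByTwo(min(t[0], t[1]), t[1], min(t[2], t[3]), t[3]))


def stratified(max_n=12):
    return st.tuples(twobytwo(max_n), twobytwo(max_n)).filter(
        lambda p: p[0].total + p[1].total > 0).map(
        lambda p: SexStratifiedCounts(male=p[0], female=p[1]))


class TestFisherOneSided:
    def test_enumerated_example(self):
        t = TwoByTwo(2, 7, 0, 7)
        assert fisher_one_sided(t).p_value == pytest.approx(
            0.230769, abs=1e-6)
        assert fisher_one_sided(t, mid=True).p_value == pytest.approx(
            0.115385, abs=1e-6)

    def test_degenerate_no_events(self):
        t = TwoByTwo(0, 7, 0, 7)
        assert fisher_one_sided(t).p_value == 1.0
        assert fisher_one_sided(t, mid=True).p_value == 0.5

    def test_agrees_with_scipy(self):
        from scipy.stats import fisher_exact
        t = TwoByTwo(5, 9, 1, 11)
        expected = fisher_exact([[5, 4], [1, 10]], alternative="greater")[1]
        assert fisher_one_sided(t).p_value == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(twobytwo())
    def test_oracle_and_mid_dominance(self, t):
        p_std = fisher_one_sided(t).p_value
        p_mid = fisher_one_sided(t, mid=True).p_value
        assert p_std == pytest.approx(oracle_fisher_one_sided(t, False),
                                      abs=1e-10)
        assert p_mid == pytest.approx(oracle_fisher_one_sided(t, True),
                                      abs=1e-10)
        assert p_mid <= p_std + 1e-12
        # mid-P sits within half the maximum point probability of standard P
        lo, pmf = _hypergeom_pmf(t.total_a, t.total_b, t.total_events)
        assert p_mid >= p_std - max(pmf) - 1e-12

    def test_standard_p_superuniform_on_conditional_law(self):
        # P(p <= alpha) <= alpha exactly, computed over the null law itself
        for (na, nb, m) in [(7, 7, 3), (7, 721, 10), (5, 9, 6)]:
            lo, pmf = _hypergeom_pmf(na, nb, m)
            for alpha in (0.01, 0.05, 0.2):
                mass = sum(
                    w for k, w in enumerate(pmf)
                    if fisher_one_sided(
                        TwoByTwo(lo + k, na, m - (lo + k), nb)).p_value
                    <= alpha)
                assert mass <= alpha + 1e-12


class TestFeStage1:
    def test_min_doubled(self):
        d = SexStratifiedCounts(male=TwoByTwo(2, 7, 0, 7),
                                female=TwoByTwo(0, 7, 0, 7))
        # male mid p = 0.115385, female degenerate mid 0.5
        assert fe_stage1(d, mid=True).p_value == pytest.approx(
            0.230769, abs=1e-6)

    def test_cap_at_one(self):
        d = SexStratifiedCounts(male=TwoByTwo(0, 7, 0, 7),
                                female=TwoByTwo(0, 7, 0, 7))
        assert fe_stage1(d, mid=False).p_value == 1.0

    def test_symmetric_strata_double_common_p(self):
        t = TwoByTwo(3, 7, 1, 10)
        d = SexStratifiedCounts(male=t, female=t)
        single = fisher_one_sided(t).p_value
        assert fe_stage1(d).p_value == pytest.approx(min(1, 2 * single))

    def test_single_sex_not_doubled_with_warning(self):
        d = SexStratifiedCounts(male=TwoByTwo(2, 7, 0, 7),
                                female=TwoByTwo(0, 0, 0, 0))
        r = fe_stage1(d, mid=True)
        assert r.p_value == pytest.approx(0.115385, abs=1e-6)
        assert r.warnings


class TestMantelHaenszel:
    def test_single_informative_stratum_reduces_to_fisher(self):
        t = TwoByTwo(3, 7, 1, 10)
        d = SexStratifiedCounts(male=t, female=TwoByTwo(0, 7, 0, 7))
        assert mh_exact_mid(d).p_value == pytest.approx(
            fisher_one_sided(t, mid=True).p_value, abs=1e-12)

    def test_degenerate(self):
        d = SexStratifiedCounts(male=TwoByTwo(0, 7, 0, 7),
                                female=TwoByTwo(0, 7, 0, 7))
        assert mh_exact_mid(d).p_value == 0.5
        assert mh_exact_mid(d, mid=False).p_value == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(stratified(10))
    def test_enumeration_oracle_and_symmetry(self, d):
        for mid in (False, True):
            p = mh_exact_mid(d, mid=mid).p_value
            assert p == pytest.approx(oracle_mh(d, mid), abs=1e-10)
            p_sw = mh_exact_mid(d.swap_sexes(), mid=mid).p_value
            assert p == pytest.approx(p_sw, abs=1e-12)

    def test_conditional_law_normalized(self):
        for (na, nb, m) in [(7, 7, 5), (7, 721, 40), (12, 3, 9)]:
            _, pmf = _hypergeom_pmf(na, nb, m)
            assert abs(sum(pmf) - 1.0) <= 1e-12


class TestZelen:
    def test_no_events_p_one(self):
        d = SexStratifiedCounts(male=TwoByTwo(0, 7, 0, 7),
                                female=TwoByTwo(0, 7, 0, 7))
        assert zelen_mid(d).p_value == 1.0

    def test_identical_strata_modal_standard_p_one(self):
        t = TwoByTwo(2, 7, 2, 20)
        d = SexStratifiedCounts(male=t, female=t)
        assert zelen_mid(d, mid=False).p_value == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(stratified(10))
    def test_enumeration_oracle(self, d):
        for mid in (False, True):
            p = zelen_mid(d, mid=mid).p_value
            assert p == pytest.approx(max(oracle_zelen(d, mid),
                                          np.nextafter(0, 1)), abs=1e-10)


class TestFeKo:
    def test_equal_sexes_standard_modal(self):
        d = SexStratifiedCounts(male=TwoByTwo(3, 7, 0, 7),
                                female=TwoByTwo(3, 7, 0, 7))
        assert fe_ko(d, mid=False).p_value == pytest.approx(1.0)
        assert fe_ko(d, mid=True).p_value < 1.0

    def test_no_abnormalities_p_one(self):
        d = SexStratifiedCounts(male=TwoByTwo(0, 7, 0, 7),
                                female=TwoByTwo(0, 7, 0, 7))
        assert fe_ko(d).p_value == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(stratified(12))
    def test_enumeration_oracle(self, d):
        for mid in (False, True):
            p = fe_ko(d, mid=mid).p_value
            assert p == pytest.approx(max(oracle_fe_ko(d, mid),
                                          np.nextafter(0, 1)), abs=1e-10)


def test_all_tests_return_valid_p():
    d = SexStratifiedCounts(male=TwoByTwo(7, 7, 0, 7),
                            female=TwoByTwo(0, 7, 0, 7))
    for fn in (lambda x: fisher_one_sided(x.male),
               fe_stage1, mh_exact_mid, zelen_mid, fe_ko):
        p = fn(d).p_value
        assert 0 < p <= 1


def test_inconsistent_counts_rejected():
    with pytest.raises(ValidationError):
        TwoByTwo(8, 7, 0, 7)
    with pytest.raises(ValidationError):
        TwoByTwo(-1, 7, 0, 7)
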