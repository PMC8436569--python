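"""The five objective measures and the useful/redundant verdict."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aarules import (
    AssociationRule,
    CountingMode,
    Probabilities,
    ProteinSequence,
    RuleMetrics,
    bi_confidence,
    bi_improve,
    bi_lift,
    classify,
    generate_random_protein,
    improve,
    lift,
    partition,
)
from aarules.interestingness import REDUNDANT, UNDEFINED, USEFUL

from conftest import contingency

PAPER, SET = CountingMode.PAPER, CountingMode.SET


def probs(ant, cons, db, mode=PAPER):
    return Probabilities.from_rule(AssociationRule(tuple(ant), tuple(cons)), db, mode)


class TestPublishedHbbValues:
    """Measure values printed for the hemoglobin beta run, to 3 decimals."""

    @pytest.mark.parametrize(
        "ant,cons,exp_lift,exp_bilift,exp_biimp,exp_biconf",
        [
            ("GT", "AN", 3.75, 12.0, 0.183, 0.917),
            ("AN", "GK", 3.0, 11.0, 0.242, 0.909),
            ("GS", "FL", 3.0, 6.0, 0.167, 0.833),
            ("GH", "A", 1.0, 1.0, 0.0, 0.0),
            ("PT", "V", 0.833, 0.786, -0.073, -0.273),
            ("FG", "L", 0.833, 0.769, -0.1, -0.3),
        ],
    )
    def test_measure_quadruple(self, hbb_db, ant, cons, exp_lift, exp_bilift, exp_biimp, exp_biconf):
        p = probs(ant, cons, hbb_db)
        assert round(float(lift(p)), 3) == exp_lift
        assert round(float(bi_lift(p)), 3) == exp_bilift
        assert round(float(bi_improve(p)), 3) == exp_biimp
        assert round(float(bi_confidence(p)), 3) == exp_biconf

    def test_improve_for_worked_example(self, hbb_db):
        # conf(GT→AN)=1 and P(AN)=4/15, so improve = 11/15
        assert improve(probs("GT", "AN", hbb_db)) == Fraction(11, 15)
        # conf(GH→A)=1 and occurrence-based P(A)=1, so improve vanishes
        assert improve(probs("GH", "A", hbb_db)) == 0

    def test_lift_of_fg_to_l_uses_occurrence_based_consequent(self, hbb_db):
        p = probs("FG", "L", hbb_db)
        assert p.p_b == Fraction(18, 15)  # occurrence basis may exceed 1
        assert lift(p) == Fraction(15, 18)


class TestVerdict:
    def test_worked_example_is_useful(self, hbb_db):
        p = probs("GT", "AN", hbb_db)
        assert RuleMetrics.from_probabilities(p).verdict == USEFUL

    def test_exact_independence_is_redundant(self, hbb_db):
        p = probs("GH", "A", hbb_db)
        m = RuleMetrics.from_probabilities(p)
        assert (m.lift, m.bi_lift, m.bi_improve, m.bi_confidence) == (1, 1, 0, 0)
        assert m.verdict == REDUNDANT

    def test_negative_correlation_is_redundant(self, hbb_db):
        assert RuleMetrics.from_probabilities(probs("FG", "L", hbb_db)).verdict == REDUNDANT

    def test_undefined_component_fails_its_clause(self):
        assert classify(2.0, None, None, 0.5, 0.5) == REDUNDANT
        assert classify(3.75, None, 12.0, 0.183, 0.917) == USEFUL  # improve unused

    def test_infinite_bi_lift_passes(self):
        assert classify(2.0, 0.5, math.inf, 0.25, 1.0) == USEFUL


class TestDegenerateDatabases:
    def test_exact_independence_synthetic_db(self):
        # windows AC | AD | CG | DG: P(A)=P(C)=1/2, P(AC)=1/4 = P(A)P(C)
        db = partition(ProteinSequence("ind", "ACADCGDG"), 2)
        p = probs("A", "C", db, SET)
        assert lift(p) == 1 and bi_lift(p) == 1
        assert improve(p) == 0 and bi_improve(p) == 0 and bi_confidence(p) == 0

    def test_consequent_only_with_antecedent_gives_infinite_bi_lift(self):
        # C occurs only in windows that also contain A
        db = partition(ProteinSequence("inf", "ACACDGDG"), 2)
        p = probs("A", "C", db, SET)
        assert bi_lift(p) == math.inf
        assert RuleMetrics.from_probabilities(p).verdict == USEFUL

    def test_antecedent_in_every_window_is_undefined(self):
        db = partition(ProteinSequence("all", "ACADAGAC"), 2)
        p = probs("A", "C", db, SET)
        assert p.p_not_a == 0
        assert bi_lift(p) is UNDEFINED
        assert bi_improve(p) is UNDEFINED
        assert bi_confidence(p) is UNDEFINED
        assert RuleMetrics.from_probabilities(p).verdict == REDUNDANT


class TestOracleAndProperties:
    def _random_pairs(self, db):
        letters = sorted(set().union(*(w.letter_set for w in db.windows)))
        for i, a in enumerate(letters):
            for b in letters[i + 1 :]:
                yield (a,), (b,)

    def test_contingency_table_oracle_set_mode(self, random_db):
        db = random_db(length=100, seed=17)
        n = db.n_windows
        for ant, cons in self._random_pairs(db):
            n11, n10, n01, n00 = contingency(ant, cons, db)
            na, nb = n11 + n10, n11 + n01
            if not (0 < na < n and nb > 0):
                continue
            p = probs(ant, cons, db, SET)
            assert lift(p) == Fraction(n * n11, na * nb)
            assert improve(p) == Fraction(n11, na) - Fraction(nb, n)
            if n01 > 0:
                assert bi_lift(p) == Fraction(n11 * (n - na), na * n01)
            else:
                assert bi_lift(p) == math.inf or bi_lift(p) is UNDEFINED
            assert bi_improve(p) == Fraction(n11 * n - na * nb, n * (n - na))
            assert bi_confidence(p) == Fraction(n11 * n - na * nb, na * (n - na))

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        length=st.integers(20, 120),
        mode=st.sampled_from([PAPER, SET]),
    )
    def test_sign_coherence(self, seed, length, mode):
        db = partition(generate_random_protein(length, seed), 10)
        letters = sorted(set().union(*(w.letter_set for w in db.windows)))
        for ant, cons in [((letters[0],), (letters[-1],)), ((letters[0], letters[1]), (letters[-1],))]:
            if set(ant) & set(cons):
                continue
            p = probs(ant, cons, db, mode)
            if p.p_a == 0 or p.p_b == 0 or p.p_not_a == 0 or p.p_a_window == 0:
                continue
            delta = p.p_ab - p.p_a * p.p_b
            assert (bi_improve(p) > 0) == (delta > 0)
            assert (bi_confidence(p) > 0) == (delta > 0)
            assert (bi_improve(p) == 0) == (delta == 0)
            assert (lift(p) > 1) == (delta > 0)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), length=st.integers(20, 120))
    def test_set_mode_bi_confidence_range(self, seed, length):
        db = partition(generate_random_protein(length, seed), 10)
        letters = sorted(set().union(*(w.letter_set for w in db.windows)))
        for ant in letters[:4]:
            for cons in letters[-4:]:
                if ant == cons:
                    continue
                p = probs((ant,), (cons,), db, SET)
                value = bi_confidence(p)
                if value is not UNDEFINED:
                    assert -1 <= value <= 1
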