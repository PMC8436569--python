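"""Objective interestingness measures and the useful/redundant verdict.

For a strong rule A → B over n windows the measures are

    lift          = P(AB) / (P(A) P(B))
    improve       = P(B|A) - P(B)
    bi-lift       = lift(A → B) / lift(Ā → B)
    bi-improve    = (P(AB) - P(A) P(B)) / P(Ā)
    bi-confidence = (P(AB) - P(A) P(B)) / (P(A) (1 - P(A)))

A rule is *useful* iff lift > 1, bi-lift > 1, bi-improve > 0 and
bi-confidence > 0, all strict; otherwise it is *redundant*.  Rules at exact
independence (1, 1, 0, 0) are therefore redundant.

Probability conventions.  P(AB) is always the window-containment fraction of
A ∪ B.  P(A) and P(B) use the active counting mode's support (so in paper
mode a singleton side uses its occurrence count and may exceed 1; this is
deliberate and reproduces the published tables).  P(Ā) and the bi-confidence
denominator always use the antecedent's *window-containment* probability,
and P(ĀB) is computed as P(B) - P(AB) rather than by direct counting — in
set mode the two coincide; in paper mode only this difference reproduces the
published bi-lift values for occurrence-based consequents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .apriori import CountingMode, support_count, window_containment_count
from .errors import UndefinedMetricError
from .rules import AssociationRule
from .sequence_io import TransactionDB

USEFUL = "useful"
REDUNDANT = "redundant"

#: Marker for a measure whose denominator vanishes.
UNDEFINED = None


@dataclass(frozen=True)
class Probabilities:
    """The probability ingredients of the five measures for one rule."""

    p_a: Fraction          # antecedent, active-mode support / n_windows
    p_b: Fraction          # consequent, active-mode support / n_windows
    p_ab: Fraction         # window-containment of A ∪ B / n_windows
    p_a_window: Fraction   # window-containment of A / n_windows
    p_not_a: Fraction      # 1 - p_a_window
    p_nota_b: Fraction     # P(B) - P(AB)

    @classmethod
    def from_rule(
        cls,
        rule: AssociationRule,
        db: TransactionDB,
        mode: CountingMode = CountingMode.PAPER,
    ) -> "Probabilities":
        mode = CountingMode.coerce(mode)
        n = db.n_windows
        if n == 0:
            raise UndefinedMetricError("empty transaction database")
        p_a = Fraction(support_count(rule.antecedent, db, mode), n)
        p_b = Fraction(support_count(rule.consequent, db, mode), n)
        p_ab = Fraction(window_containment_count(rule.union, db), n)
        p_a_window = Fraction(window_containment_count(rule.antecedent, db), n)
        return cls(p_a, p_b, p_ab, p_a_window, 1 - p_a_window, p_b - p_ab)


def lift(p: Probabilities):
    """P(AB) / (P(A) P(B)); None when a marginal is zero."""
    if p.p_a == 0 or p.p_b == 0:
        return UNDEFINED
    return p.p_ab / (p.p_a * p.p_b)


def improve(p: Probabilities):
    """P(B|A) - P(B); None when P(A) is zero."""
    if p.p_a == 0:
        return UNDEFINED
    return p.p_ab / p.p_a - p.p_b


def bi_lift(p: Probabilities):
    """lift(A → B) / lift(Ā → B), i.e. P(AB) P(Ā) / (P(A) P(ĀB)).

    Returns +inf when P(ĀB) == 0 but the rule itself has positive lift
    (perfect asymmetry), and None when P(Ā) == 0 (antecedent in every
    window) or a marginal vanishes.
    """
    base = lift(p)
    if base is UNDEFINED or p.p_not_a == 0:
        return UNDEFINED
    if p.p_nota_b == 0:
        return math.inf if base > 0 else UNDEFINED
    return (p.p_ab * p.p_not_a) / (p.p_a * p.p_nota_b)


def bi_improve(p: Probabilities):
    """(P(AB) - P(A) P(B)) / P(Ā); None when the antecedent fills every window."""
    if p.p_not_a == 0:
        return UNDEFINED
    return (p.p_ab - p.p_a * p.p_b) / p.p_not_a


def bi_confidence(p: Probabilities):
    """(P(AB) - P(A) P(B)) / (P(A)(1 - P(A))), window-based denominator.

    None when the antecedent is in zero or all windows.
    """
    denom = p.p_a_window * (1 - p.p_a_window)
    if denom == 0:
        return UNDEFINED
    return (p.p_ab - p.p_a * p.p_b) / denom


@dataclass(frozen=True)
class RuleMetrics:
    """All five measures plus the usefulness verdict for one rule."""

    lift: object
    improve: object
    bi_lift: object
    bi_improve: object
    bi_confidence: object
    verdict: str

    @classmethod
    def from_probabilities(cls, p: Probabilities) -> "RuleMetrics":
        values = (lift(p), improve(p), bi_lift(p), bi_improve(p), bi_confidence(p))
        return cls(*values, verdict=classify(*values))


def classify(lift_v, improve_v, bi_lift_v, bi_improve_v, bi_conf_v) -> str:
    """Useful iff lift > 1, bi-lift > 1, bi-improve > 0, bi-confidence > 0.

    All four clauses are strict; an undefined component fails its clause.
    ``improve`` is reported but deliberately not part of the verdict.
    """
    clauses = (
        lift_v is not UNDEFINED and lift_v > 1,
        bi_lift_v is not UNDEFINED and bi_lift_v > 1,
        bi_improve_v is not UNDEFINED and bi_improve_v > 0,
        bi_conf_v is not UNDEFINED and bi_conf_v > 0,
    )
    return USEFUL if all(clauses) else REDUNDANT


def score_rules(rules: list, db: TransactionDB, mode: CountingMode = CountingMode.PAPER) -> list:
    """Compute :class:`RuleMetrics` for each rule; returns (rule, metrics) pairs."""
    out = []
    for rule in rules:
        p = Probabilities.from_rule(rule, db, mode)
        out.append((rule, RuleMetrics.from_probabilities(p)))
    return out


def _fmt(value) -> str:
    if value is UNDEFINED:
        return "undefined"
    if value == math.inf:
        return "inf"
    return f"{float(value):.3f}"


def write_metrics_tsv(scored: list, path) -> None:
    """Dump (rule, metrics) pairs as TSV, useful first, descending bi-confidence."""
    from .rules import confidence_pct

    def sort_key(pair):
        rule, m = pair
        useful_first = 0 if m.verdict == USEFUL else 1
        bc = m.bi_confidence
        bc = -math.inf if bc is UNDEFINED else float(bc)
        return (useful_first, -bc)

    ordered = sorted(scored, key=sort_key)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "antecedent\tconsequent\tconfidence_pct\tlift\tbi_lift\t"
            "bi_improve\tbi_confidence\tverdict\n"
        )
        for rule, m in ordered:
            pct = confidence_pct(rule.confidence) if rule.confidence is not None else ""
            fh.write(
                f"{''.join(rule.antecedent)}\t{''.join(rule.consequent)}\t{pct}\t"
                f"{_fmt(m.lift)}\t{_fmt(m.bi_lift)}\t{_fmt(m.bi_improve)}\t"
                f"{_fmt(m.bi_confidence)}\t{m.verdict}\n"
            )
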