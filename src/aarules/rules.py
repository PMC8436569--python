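"""Association-rule enumeration, confidence, and strong-rule filtering.

Every frequent itemset of size k >= 2 yields all 2^k - 2 antecedent →
consequent partitions (nonempty proper subsets as antecedents, complement as
consequent).  Confidence is held as an exact ``Fraction`` of support counts —
supp(A ∪ B) / supp(A) under the active counting mode — and only rendered as a
rounded percentage for display; filtering uses the exact value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from itertools import combinations

from .apriori import CountingMode, FrequentItemsetTable, support_count
from .errors import ValidationError
from .sequence_io import TransactionDB

#: Default confidence threshold: a rule is strong at >= 90%.
DEFAULT_MIN_CONF = Fraction(9, 10)

ACCEPTED = "accepted"
REJECTED = "rejected"


@dataclass(frozen=True)
class AssociationRule:
    """A disjoint antecedent/consequent split of a frequent itemset."""

    antecedent: tuple
    consequent: tuple
    confidence: Fraction | None = None
    status: str | None = None

    @property
    def union(self) -> tuple:
        return tuple(sorted(self.antecedent + self.consequent))

    def __str__(self) -> str:
        return f"{''.join(self.antecedent)} -> {''.join(self.consequent)}"


def confidence_pct(conf: Fraction) -> int:
    """Whole-percent display value, rounding half away from zero."""
    scaled = conf * 100
    return int((scaled + Fraction(1, 2)).__floor__())


def enumerate_rules(table: FrequentItemsetTable) -> list:
    """All candidate rules from every frequent itemset of size >= 2.

    Rules are grouped by source itemset (sizes ascending, lexicographic
    within a size); within a group antecedents are ordered lexicographically
    as letter strings, matching the published rule serials.
    """
    rules = []
    for its in table.all_itemsets():
        k = its.size
        if k < 2:
            continue
        antecedents = []
        for r in range(1, k):
            antecedents.extend(combinations(its.letters, r))
        antecedents.sort(key="".join)
        for ant in antecedents:
            cons = tuple(x for x in its.letters if x not in ant)
            rules.append(AssociationRule(ant, cons))
    return rules


def confidence(rule: AssociationRule, db: TransactionDB, mode: CountingMode) -> Fraction:
    """Exact confidence supp(A ∪ B) / supp(A) under the active mode."""
    if not rule.antecedent or not rule.consequent:
        raise ValidationError("rule sides must be nonempty")
    if set(rule.antecedent) & set(rule.consequent):
        raise ValidationError(f"rule sides overlap: {rule}")
    denom = support_count(rule.antecedent, db, mode)
    if denom == 0:
        raise ZeroDivisionError(f"antecedent of {rule} has zero support")
    return Fraction(support_count(rule.union, db, mode), denom)


def score_confidences(rules: list, db: TransactionDB, mode: CountingMode) -> list:
    """Return the rules with their exact confidences filled in."""
    return [replace(r, confidence=confidence(r, db, mode)) for r in rules]


def filter_strong(rules: list, min_conf: Fraction = DEFAULT_MIN_CONF) -> tuple:
    """Partition scored rules into (accepted, rejected) at ``min_conf``.

    The comparison is inclusive (a rule at exactly the threshold passes);
    input order is preserved within each partition.
    """
    accepted, rejected = [], []
    for rule in rules:
        if rule.confidence is None:
            raise ValidationError(f"rule {rule} has no confidence; score it first")
        if rule.confidence >= min_conf:
            accepted.append(replace(rule, status=ACCEPTED))
        else:
            rejected.append(replace(rule, status=REJECTED))
    return accepted, rejected


def write_rules_tsv(rules: list, db: TransactionDB, mode: CountingMode, path) -> None:
    """Dump scored rules as TSV with exact and percent confidences."""
    mode = CountingMode.coerce(mode)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "antecedent\tconsequent\tsupport_count_union\t"
            "confidence_exact\tconfidence_pct\tstatus\n"
        )
        for r in rules:
            union_supp = support_count(r.union, db, mode)
            fh.write(
                f"{''.join(r.antecedent)}\t{''.join(r.consequent)}\t{union_supp}\t"
                f"{r.confidence.numerator}/{r.confidence.denominator}\t"
                f"{confidence_pct(r.confidence)}\t{r.status or ''}\n"
            )
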