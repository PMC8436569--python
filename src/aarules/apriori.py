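"""Levelwise Apriori mining of frequent amino-acid itemsets.

Two counting modes are supported:

``set``
    Classical market-basket semantics: the support of any itemset is the
    number of windows whose distinct-letter set contains it.

``paper``
    The convention used by the publication this pipeline reproduces: the
    support of a 1-itemset is the total occurrence count of the letter across
    all windows (with multiplicity, i.e. its count in the whole sequence),
    while k-itemsets for k >= 2 are counted by window containment exactly as
    in ``set`` mode.  The occurrence basis for singletons is what makes the
    published confidences (e.g. 43% for a letter occurring 7 times but
    present in only 5 windows) come out.

``minsup`` is an absolute support *count*, not a fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

from .errors import ValidationError
from .sequence_io import AMINO_ACIDS, TransactionDB

_AA_SET = frozenset(AMINO_ACIDS)


class CountingMode(str, Enum):
    """How itemset support is counted; see the module docstring."""

    PAPER = "paper"
    SET = "set"

    @classmethod
    def coerce(cls, value) -> "CountingMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValidationError(
                f"unknown counting mode {value!r}; expected 'paper' or 'set'"
            ) from None


@dataclass(frozen=True)
class Itemset:
    """A sorted set of distinct amino-acid letters with its support count."""

    letters: tuple
    support_count: int

    @property
    def size(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return "".join(self.letters)


@dataclass(frozen=True)
class FrequentItemsetTable:
    """Frequent itemsets grouped by size, as produced by :func:`apriori`."""

    by_size: dict
    minsup: int
    mode: CountingMode
    n_windows: int

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.by_size.values())

    @property
    def max_size(self) -> int:
        return max(self.by_size, default=0)

    def all_itemsets(self):
        """Iterate itemsets by size, then lexicographically within a size."""
        for k in sorted(self.by_size):
            yield from self.by_size[k]


def _validate_items(items) -> tuple:
    items = tuple(items)
    if not items:
        raise ValidationError("itemset must be nonempty")
    if len(set(items)) != len(items):
        raise ValidationError(f"duplicate letters in itemset {items!r}")
    bad = set(items) - _AA_SET
    if bad:
        raise ValidationError(f"invalid letters in itemset: {sorted(bad)}")
    return tuple(sorted(items))


def window_containment_count(items, db: TransactionDB) -> int:
    """Number of windows whose distinct-letter set contains all of ``items``."""
    needed = frozenset(items)
    return sum(1 for w in db.windows if needed <= w.letter_set)


def support_count(items, db: TransactionDB, mode: CountingMode = CountingMode.PAPER) -> int:
    """Support count of an itemset under the active counting mode."""
    items = _validate_items(items)
    mode = CountingMode.coerce(mode)
    if mode is CountingMode.PAPER and len(items) == 1:
        return db.occurrences[items[0]]
    return window_containment_count(items, db)


def find_frequent_length1(db: TransactionDB, minsup: int, mode: CountingMode) -> list:
    """All single letters whose support meets ``minsup``, alphabetically."""
    if minsup < 1:
        raise ValidationError(f"minsup must be >= 1, got {minsup}")
    mode = CountingMode.coerce(mode)
    out = []
    for letter in AMINO_ACIDS:
        count = support_count((letter,), db, mode)
        if count >= minsup:
            out.append(Itemset((letter,), count))
    return out


def candidate_join(prev_level: list) -> list:
    """Join (k-1)-itemsets sharing their first k-2 letters into k-candidates.

    Returns sorted, duplicate-free letter tuples.  For k == 2 (singleton
    input) this is simply every pair of frequent letters.
    """
    if not prev_level:
        return []
    sizes = {its.size for its in prev_level}
    if len(sizes) != 1:
        raise ValidationError(f"mixed itemset sizes in level: {sorted(sizes)}")
    tuples = sorted(its.letters for its in prev_level)
    candidates = set()
    for a, b in combinations(tuples, 2):
        if a[:-1] == b[:-1]:
            candidates.add(tuple(sorted(set(a) | set(b))))
    return sorted(candidates)


def _closure_prune(candidates, prev_letters: set) -> list:
    return [
        c
        for c in candidates
        if all(tuple(sub) in prev_letters for sub in combinations(c, len(c) - 1))
    ]


def apriori(db: TransactionDB, minsup: int, mode: CountingMode = CountingMode.PAPER) -> FrequentItemsetTable:
    """Mine all frequent itemsets by levelwise expansion until a level is empty.

    In set mode candidates are additionally pruned by the (k-1)-subset closure
    test before counting; in paper mode the singleton level is counted on a
    different basis (occurrences), so level-2 candidates are all pairs of
    frequent letters and every joined candidate is counted directly.
    """
    if minsup < 1:
        raise ValidationError(f"minsup must be >= 1, got {minsup}")
    mode = CountingMode.coerce(mode)
    by_size = {}
    level = find_frequent_length1(db, minsup, mode)
    k = 1
    while level:
        by_size[k] = level
        candidates = candidate_join(level)
        if mode is CountingMode.SET and k >= 2:
            candidates = _closure_prune(candidates, {its.letters for its in level})
        k += 1
        level = []
        for cand in candidates:
            count = window_containment_count(cand, db)
            if count >= minsup:
                level.append(Itemset(cand, count))
    return FrequentItemsetTable(by_size, minsup, mode, db.n_windows)


def write_itemsets_tsv(table: FrequentItemsetTable, path) -> None:
    """Dump the table as TSV: (size, itemset, support_count, support_fraction)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("size\titemset\tsupport_count\tsupport_fraction\n")
        for its in table.all_itemsets():
            frac = its.support_count / table.n_windows if table.n_windows else 0.0
            fh.write(f"{its.size}\t{its}\t{its.support_count}\t{frac:.6f}\n")
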