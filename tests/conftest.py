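"""Shared fixtures and independent brute-force oracles.

The oracles recount everything directly over the window list (exhaustive
subset enumeration, direct ratio arithmetic) so they share no code path with
the levelwise miner or the rule engine they check.
"""

from collections import Counter
from fractions import Fraction
from itertools import combinations

import pytest

from aarules import (
    CountingMode,
    generate_random_protein,
    hbb_fixture_path,
    partition,
    read_fasta,
)


@pytest.fixture(scope="session")
def hbb_seq():
    (seq,) = read_fasta(hbb_fixture_path())
    return seq


@pytest.fixture(scope="session")
def hbb_db(hbb_seq):
    return partition(hbb_seq, 10)


@pytest.fixture
def random_db():
    def make(length=60, seed=11, window_len=10):
        return partition(generate_random_protein(length, seed), window_len)

    return make


# ---------------------------------------------------------------- oracles


def brute_support(items, db, mode):
    """Direct support count: scan every window, no levelwise machinery."""
    items = tuple(sorted(items))
    if CountingMode.coerce(mode) is CountingMode.PAPER and len(items) == 1:
        return sum(w.residues.count(items[0]) for w in db.windows)
    return sum(1 for w in db.windows if set(items) <= w.letter_set)


def brute_frequent_itemsets(db, minsup, mode):
    """All frequent itemsets by exhaustive enumeration of observed letters."""
    letters = sorted(set().union(*(w.letter_set for w in db.windows)) if db.windows else set())
    out = {}
    max_size = max((len(w.letter_set) for w in db.windows), default=0)
    for k in range(1, max(max_size, 1) + 1):
        level = {
            c: brute_support(c, db, mode)
            for c in combinations(letters, k)
            if brute_support(c, db, mode) >= minsup
        }
        if level:
            out[k] = level
    return out


def brute_confidence(antecedent, consequent, db, mode):
    union = tuple(sorted(antecedent + consequent))
    return Fraction(brute_support(union, db, mode), brute_support(antecedent, db, mode))


def contingency(a_items, b_items, db):
    """2x2 window-containment table for antecedent vs consequent (set view)."""
    a, b = set(a_items), set(b_items)
    n11 = sum(1 for w in db.windows if a <= w.letter_set and b <= w.letter_set)
    n10 = sum(1 for w in db.windows if a <= w.letter_set and not b <= w.letter_set)
    n01 = sum(1 for w in db.windows if not a <= w.letter_set and b <= w.letter_set)
    n00 = db.n_windows - n11 - n10 - n01
    return n11, n10, n01, n00
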