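# Methods

## Pipeline

The pipeline has five stages, each a thin layer over the previous one:

1. **Input.** Protein sequences are read from FASTA (`aarules.sequence_io`,
   via Bio.SeqIO). The id is the header token before the first whitespace.
   Residues are upper-cased and validated against the 20-letter alphabet.
   Strict mode (default) rejects non-standard characters (B, J, O, U, X, Z,
   `*`, …) with their 1-based position; lenient mode drops them with a
   logged warning. The bundled fixture is the 147-residue human hemoglobin
   subunit beta chain (UniProt P68871), which contains none.
2. **Windowing.** The sequence is cut into consecutive, non-overlapping
   windows of `window_len` residues (default 10). The trailing partial
   window is kept as a transaction — for hemoglobin beta this is the
   7-residue tail and the window count is ceil(147/10) = 15. Overlapping or
   randomised windowing is deliberately out of scope. Each window carries
   both its residue multiset and its distinct-letter set.
3. **Mining.** Levelwise Apriori (`aarules.apriori`) with an absolute
   minimum support *count* (not a fraction). Level k candidates are formed
   by joining two frequent (k−1)-itemsets sharing their first k−2 letters;
   expansion stops when a level is empty. The algorithm is fully
   deterministic; itemsets are kept alphabetically sorted and listed by
   size, then lexicographically.
4. **Rules.** Every frequent k-itemset (k ≥ 2) yields all 2^k − 2
   antecedent/consequent partitions (`aarules.rules`). Rules are generated
   from *all* frequent itemsets, not only maximal ones. Confidence is held
   as an exact `Fraction` of integer support counts; filtering at the
   threshold (default 90%) compares exact ratios and is inclusive — a rule
   at exactly 90% is accepted. Display rounds to the nearest whole percent,
   half away from zero.
5. **Usefulness.** Each strong rule gets lift, improve, bi-lift,
   bi-improve and bi-confidence (`aarules.interestingness`) and the verdict
   *useful* iff lift > 1 ∧ bi-lift > 1 ∧ bi-improve > 0 ∧ bi-confidence > 0,
   all strict. A rule at exact independence scores (1, 1, 0, 0) and is
   redundant. `improve` is computed and reported but not part of the
   verdict: its sign always matches bi-improve's, so the published
   accept/reject outcomes cannot distinguish whether it was ever consulted.

## Counting modes

`set` mode is the classical market-basket semantics: the support of any
itemset is the number of windows whose letter set contains it. All standard
properties hold (anti-monotonicity, bi-confidence ∈ [−1, 1]), and candidate
generation additionally applies the (k−1)-subset closure prune.

`paper` mode (the default) reproduces the published convention, which the
set semantics cannot: singleton support is the letter's total occurrence
count *with multiplicity* across all windows, while itemsets of size ≥ 2
are counted by window containment. This is what makes confidences like
"D → A = 43%" come out: D occurs 7 times in the sequence but appears in
only 5 windows, and 3/7 ≈ 43%. The two modes agree exactly on every
itemset of size ≥ 2. Because occurrence counts can exceed the window
count, a paper-mode singleton "probability" may exceed 1 (e.g. P(L) = 18/15
on hemoglobin beta); this is intentional and documented on the
`Probabilities` container. In paper mode no closure prune is applied —
level-2 candidates are all pairs of frequent letters and every joined
candidate is counted directly — because the singleton level is counted on a
different basis. Whether the singleton threshold was originally applied to
occurrence or window counts is indistinguishable on the hemoglobin run (no
letter separates the two at support count 3); occurrence counts are used,
matching the single dataset pass of the levelwise procedure.

## Probability conventions for the measures

For a rule A → B over n windows:

- P(AB) is always the window-containment fraction of A ∪ B (a union of two
  nonempty disjoint sides has size ≥ 2, so both modes agree here).
- P(A) and P(B) use the active mode's support, so paper-mode singleton
  sides use the occurrence basis.
- P(Ā) and the bi-confidence denominator always use the antecedent's
  *window-containment* probability, even in paper mode. Consequently a
  paper-mode singleton antecedent's P(A) and P(Ā) need not sum to 1; both
  bases are retained in `Probabilities`.
- P(ĀB) is computed as P(B) − P(AB), not by directly counting windows that
  contain B but not A. In set mode the two coincide; in paper mode, with an
  occurrence-based P(B), only the subtraction form reproduces the published
  bi-lift values.

These conventions were fixed by requiring that every hand-checkable
published value come out exactly (the worked example GT → AN =
3.75/12/0.183/0.917 and the redundant-tail rows such as PT → V =
0.833/0.786/−0.073/−0.273), and they are the only combination consistent
with all of them.

Degenerate cases: a measure whose denominator vanishes is reported as
undefined (`None` in the API, `undefined` in TSV) and fails its verdict
clause. Bi-lift with P(ĀB) = 0 but positive lift is +∞ — the consequent
never occurs without the antecedent — which passes the bi-lift > 1 clause,
consistent with its stated [0, ∞] range.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `window_len` | 10 residues | transaction size; the study's fixed choice |
| `minsup_count` | 3 | absolute support count; study presets are 3 (147 aa), 4 (348–371 aa), 5 (1480–1863 aa), shipped as `PRESETS` |
| `min_conf` | 9/10 | strong-rule threshold, inclusive |
| `mode` | `paper` | counting mode; `set` is the principled alternative |

## Synthetic-sequence generator

`generate_random_protein(length, seed, freqs)` draws residues i.i.d. from a
given (default uniform) distribution over the 20 letters, deterministically
per seed. It emulates only sequence length and residue composition — real
proteins have positional autocorrelation, domain structure and biased
dipeptide frequencies that i.i.d. draws do not. Property tests on generated
sequences therefore establish algorithmic correctness (oracle equivalence,
anti-monotonicity, measure identities), not biological claims; the
biological anchor is the bundled real hemoglobin sequence on which every
published count is reproduced exactly.

## Testing strategy and problem sizes

Brute-force oracles live in the test suite and share no code with the
implementation: exhaustive subset enumeration over observed letters for
frequent itemsets, direct window scans for supports and confidences, and
the explicit 2×2 contingency table for all five measures in set mode.
Oracle comparisons run on random sequences of 20–120 residues, where
exhaustive enumeration is cheap; the full hemoglobin run (147 aa, 15
windows) is the end-to-end regression anchor. The per-size itemset counts
16/50/50/17/2 are pinned as a regression of this implementation. The whole
suite runs in well under a minute.

## Known limitations

- The window-boundary effect is inherited from the design: a pattern
  spanning a window border is not counted. Overlapping windows would fix
  this but are out of scope here.
- Paper-mode singleton probabilities are not probabilities (they may
  exceed 1); lift and bi-lift involving singleton sides are therefore
  scale-shifted relative to their textbook definitions. Use `set` mode for
  principled values.
- Multi-record FASTA files are mined per record; there is no aggregate
  mining across proteins.
- No closed/maximal itemset condensation and no redundancy-aware rule
  condensation; the rule list is the full 2^k − 2 enumeration.
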