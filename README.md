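# aarules

Frequent amino-acid pattern and association-rule mining for protein
sequences of misfolding diseases.

Proteins whose chains fail to fold into their native conformation cause
genetic disorders such as sickle cell anemia, cystic fibrosis and
nephrogenic diabetes insipidus. One way to characterise the disease-linked
protein is to ask which amino acids dominate it and which co-occur: the
sequence is cut into consecutive windows of 10 residues, each window is
treated as a market-basket transaction of amino-acid letters, and classical
association-rule mining is run over those transactions. `aarules`
implements that pipeline end to end: FASTA input, windowing, levelwise
Apriori mining, confidence-filtered rule generation, and pruning of the
strong rules down to the *useful* ones by objective interestingness
measures.

## Model

For an itemset X over the windows, supp(X) is its support count; for a rule
A → B with window probabilities P(·):

- **confidence** conf(A → B) = supp(A ∪ B) / supp(A); a rule is *strong*
  at conf ≥ 90%.
- **lift** = P(AB) / (P(A) P(B)) — > 1 means positive correlation.
- **improve** = P(B|A) − P(B).
- **bi-lift** = lift(A → B) / lift(Ā → B) = P(AB) P(Ā) / (P(A) P(ĀB)) —
  corrects lift's symmetry defect.
- **bi-improve** = (P(AB) − P(A) P(B)) / P(Ā).
- **bi-confidence** = (P(AB) − P(A) P(B)) / (P(A)(1 − P(A))) — sign gives
  the correlation direction, range [−1, 1] under set semantics.

A strong rule is **useful** iff lift > 1, bi-lift > 1, bi-improve > 0 and
bi-confidence > 0 (all strict); otherwise it is redundant.

Two support-counting modes are provided. `set` is the classical semantics:
support of any itemset is the number of windows containing it. `paper`
(the default) reproduces the published convention: singleton support is the
letter's total occurrence count with multiplicity, while itemsets of two or
more letters are counted by window containment. See `docs/methods.md` for
why both exist and exactly where they differ.

## Worked example

The package bundles the 147-residue human hemoglobin subunit beta sequence
(UniProt P68871, the sickle-cell-anemia protein) as a fixture:

```sh
aarules mine --fasta src/aarules/data/hbb_p68871.fasta --out out/
```

logs

```
INFO aarules: P68871: 147 aa, 15 windows, 135 frequent itemsets, 698 rules, 95 strong, 59 useful, 36 redundant
```

i.e. the sequence splits into 15 windows (14 of length 10 plus a 7-residue
tail), Apriori at minimum support count 3 finds 135 frequent itemsets
(sizes 1–5), these yield 698 candidate rules of which 95 reach 90%
confidence, and the four interestingness criteria keep 59 of those as
useful. The best useful rule is GT → AN with lift 3.75, bi-lift 12,
bi-improve 0.183 and bi-confidence 0.917: windows containing both G and T
are strongly enriched for A and N. `out/` receives `itemsets.tsv`,
`rules.tsv`, `metrics.tsv` (useful rules first, descending bi-confidence)
and a versioned `report.json`.

The same thing from Python:

```python
import aarules as aa

report = aa.run_pipeline(aa.PipelineConfig(fasta_path=str(aa.hbb_fixture_path())))
s = report.sequences[0]
print(s.total_itemsets, s.strong_rules, s.useful_rules)  # 135 95 59
```

`aarules compare --a run1/report.json --b run2/report.json` diffs the
strong/useful rule sets of two runs, e.g. across counting modes or
confidence thresholds. Per-protein minimum-support presets for the five
study proteins ship as `aarules.PRESETS` (support count 3 for the 147-aa
hemoglobin, 5 for the 1863-aa BRCA1 and 1480-aa CFTR, 4 for the 371-aa
vasopressin V2 receptor and 348-aa rhodopsin).

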