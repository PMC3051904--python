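# boolgba

Boolean-logic guilt-by-association ranking of candidate disease genes.

## The problem

Finding the genes behind a complex disease such as colorectal cancer means
triaging thousands of candidates. No single data type settles the question:
differential expression between tissue states, condition-specific
expression, and functional gene properties (tissue specificity,
transcription-factor activity, post-translational modification, kinase
activity, secretion, CpG-island methylation) each carry weak, partial
evidence. `boolgba` combines them with a deliberately simple, transparent
device: every gene is reduced to a 13-bit Boolean profile, and a candidate
is scored by how much of its profile is shared with genes already known to
cause the disease — guilt by association.

The 13 variables, in order, are:

| bits | meaning |
|------|---------|
| 1–3  | differentially expressed (DE) in each of three contrasts (carcinoma–normal, carcinoma–adenoma, carcinoma–inflammation) |
| 4–7  | condition-specific (CS) expression in normal, adenoma, carcinoma, inflammation |
| 8–13 | functional attributes: TS, TF, PTM, KIN, SEC, MET |

The profiles of the training (known disease) genes are counted into a
**probabilistic truth table**: each observed profile maps to the proportion
of training genes exhibiting it. A candidate profile is decomposed into its
**roots** — the non-empty sub-profiles present in the table — and its GBA
score is the sum of the root probabilities. Scores lie in [0, 1] and are
monotone under bitwise subset containment: a gene matching more evidence
can never score lower.

Around the core scorer the package implements the full study workflow:

- sequential ANOVA-style normalization of a genes × samples log2 matrix
  (`normalize_expression`);
- DE calling per contrast with a two-component Gaussian mixture and an
  experiment-wise FDR rule (`call_differential_expression`);
- the condition-specificity statistic with its three flagging criteria
  (`condition_specificity`);
- profile binarization, truth-table construction, scoring and ranking
  (`binarize_genes`, `build_truth_table`, `rank_candidates`);
- cross-validation of the ranking with capture/enrichment curves and
  percentile calibration (`cross_validate`, `fold_ratio`);
- per-condition co-expression networks via PCIT, the always-conserved
  network (≥ 3 of 4 conditions), resolution views, attribute subnetworks
  and power-law connectivity diagnostics (`boolgba.network`);
- regulatory impact factors RIF1/RIF2 for transcription factors
  (`rif_scores`);
- seeded synthetic generators for all inputs (`simulate_expression`,
  `simulate_attributes`), TSV/SIF readers and writers, a pipeline
  orchestrator and a `boolgba` command line.

## Worked example

The canonical example is MEF2C, a transcription factor whose profile
`0100000011001` sets four bits: DE in the carcinoma–adenoma contrast, TF,
PTM and MET. Scored against the reference truth-table excerpt bundled with
the package:

```python
from boolgba import BooleanProfile, enumerate_roots, gba_score
from boolgba.worked_example import MEF2C_PROFILE, mef2c_truth_table

table = mef2c_truth_table()
profile = BooleanProfile.from_string(MEF2C_PROFILE)
roots = enumerate_roots(profile, table)
print(f"profile : {profile.string}")
print(f"roots   : {len(roots)}")
for q in roots:
    print(f"  {q}  p = {table.entries[q]:.5f}")
print(f"GBA score = {gba_score(profile, table)}")
```

prints exactly:

```
profile : 0100000011001
roots   : 14
  0000000000001  p = 0.05094
  0000000001000  p = 0.23019
  0000000001001  p = 0.02453
  0000000010000  p = 0.10755
  0000000010001  p = 0.03396
  0000000011000  p = 0.07925
  0000000011001  p = 0.03019
  0100000000000  p = 0.01509
  0100000000001  p = 0.00377
  0100000001000  p = 0.00377
  0100000001001  p = 0.00189
  0100000010000  p = 0.00377
  0100000010001  p = 0.00189
  0100000011000  p = 0.00189
GBA score = 0.58868
```

The 14 roots are every sub-profile of `0100000011001` observed among the
training genes, and the score 0.58868 is the exact decimal sum of their
probabilities.

## Command-line pipeline

Generate a synthetic dataset and run the whole pipeline on it:

```
$ boolgba simulate --seed 1 --out demo/inputs
wrote synthetic inputs to demo/inputs

$ boolgba run --matrix demo/inputs/expression.tsv \
              --samples demo/inputs/samples.tsv \
              --attributes demo/inputs/attributes.tsv \
              --train demo/inputs/training.txt \
              --iters 200 --out demo/run
done: 356 candidates scored, 46 top candidates (summary in demo/run/summary.json)
```

`demo/run/` then holds every stage artifact — normalized means, per-contrast
DE tables, CS table, Boolean profiles, the truth table, the ranking and top
candidates, the cross-validation report, the conserved network (TSV + SIF,
with node attributes and four resolution views) and RIF scores — plus a
`summary.json`; the run above reports, among other things:

```
'n_de_per_contrast': {'Carcinoma-Adenoma': 33,
                      'Carcinoma-Inflammation': 32,
                      'Carcinoma-Normal': 33},
'n_training_used': 78,
'n_truth_table_combinations': 30,
'n_scored': 356,
'fold_ratio': 2.372609,
'network': {'n_conserved_edges': 261, 'n_conserved_nodes': 106, ...},
'rif': {'n_tfs_scored': 92, 'n_extreme': 8, ...}
```

Each stage is also exposed as its own subcommand (`expression`, `binarize`,
`score`, `validate`, `network`, `rif`); `boolgba --help` lists them.

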