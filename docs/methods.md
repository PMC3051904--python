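# Methods note

This note records the statistical model behind `boolgba`, the default
parameter choices and their rationale, the numerical decisions that affect
results, and what the synthetic validation does and does not demonstrate.

## Model and procedure

**Normalization.** The genes × samples log2 matrix is decomposed
sequentially: the per-sample (hybridization) effect is the column mean; the
per-gene effect is the row mean of the sample-adjusted values; the
gene × condition mean is the gene effect plus the condition mean of the
twice-adjusted values. Residuals average to zero within every
gene × condition cell, and the three effects plus the residual reconstruct
the input exactly. This is a parsimonious fixed-effects fit — effects are
estimated in one pass in a fixed order, not jointly.

**Differential expression.** For a contrast (A, B) the per-gene difference
of normalized condition means is modelled as a two-component normal mixture
(null vs DE) fitted by EM. A gene set is flagged at a target experiment-wise
FDR: genes are sorted by the posterior probability of the DE component, and
the flagged set is the largest prefix whose cumulative mean null posterior
stays at or below the target (default 0.01).

**Condition specificity.** For gene i, CS_ij = x_ij / Σ_j x_ij over the
four condition means (globally shifted if any mean is negative, so shares
stay in [0, 1]; genes with zero total are excluded). A gene is flagged
condition-specific in j when (1) its CS exceeds the gene-average CS in j,
(2) j is its strict maximum, and (3) its CS exceeds the leave-one-out mean
plus three leave-one-out standard deviations of the other genes' CS in j.

**Boolean profiles and GBA.** The 13 bits are the three DE flags, the four
CS flags and the six functional attributes, in that fixed order. Training
genes' profiles are counted into the probabilistic truth table (all-zero
profiles are uninformative and excluded). A candidate's score is the sum of
the probabilities of its roots — table entries q with q AND p = q. Because
table entries are disjoint events over the training set, scores lie in
[0, 1] and are monotone under bitwise subset containment.

**Validation.** Cross-validation repeatedly splits the training genes
4/5 : 1/5, rebuilds the truth table from the 4/5, and ranks the held-out
1/5 pooled with the full background (genes with all-zero profiles score 0;
ties break by ascending gene id). Capture(x) is the mean fraction of
held-out disease genes ranked in the top x % ; enrichment(x) =
capture(x)/(x/100). The calibrated percentile is the smallest x whose mean
enrichment reaches the observed disease-vs-background fold ratio of mean
GBA scores.

**Networks.** Pearson correlations are computed per condition; PCIT keeps
an edge (x, y) unless some trio (x, y, z) dominates it: with partial
correlations r_xy·z etc. and tolerance ε = mean of the three
partial-to-direct ratios, the edge is eliminated when |r_xy| ≤ |ε·r_xz| and
|r_xy| ≤ |ε·r_yz|. Edges significant in ≥ 3 of 4 conditions form the
always-conserved network, which is dissected into four resolution views and
attribute subnetworks; connectivity is summarized by degree, hubs (top 1 %
of the degree distribution), and a power-law exponent fitted by OLS on
log-binned degree frequencies (geometric bins, factor 1.5).

**RIF.** For a TF j between conditions A and B over the DE genes i,
RIF1_j = mean_i[PIF_i (r_ijA − r_ijB)²] with PIF_i = ā_i·d_i (mean abundance
times difference of condition means), and
RIF2_j = mean_i[(e_iA r_ijA)² − (e_iB r_ijB)²]. Both are z-scored across the
TF set; |z| > 2 on either score flags an extreme regulator. A TF is never
scored against itself.

## Parameter defaults and rationale

These defaults define the study conditions; they were fixed on scientific
grounds before the validation was run and are not tuned to test outcomes.

- **Sample design (8, 15, 15, 15)** across normal, adenoma, carcinoma,
  inflammation — a realistic unbalanced four-condition microarray design.
- **Expression generator**: baseline gene means Normal(8, 2) on the log2
  scale; noise SD 0.5 and hybridization-offset SD 0.3 (typical microarray
  technical variation); 30 DE genes shifted by `de_effect_sd · noise_sd`
  = 4 · 0.5 = 2.0 (a 4-fold change, a strong but realistic effect);
  5 condition-specific genes at 10-fold.
- **Attribute generator**: background attribute rates TS 0.10, TF 0.08,
  PTM 0.10, KIN 0.024, SEC 0.08, MET 0.05 (orders of magnitude of the
  corresponding genome-wide annotation classes, e.g. ~500 kinases in a
  ~21 000-gene genome); disease-set enrichment odds TS 2.5, TF 3, PTM 4,
  KIN 12, SEC 2, MET 2 (PTM ~40 % vs ~10 % and kinases ~30 % vs ~2.4 %
  among disease genes, with modest enrichment elsewhere); disease fraction
  0.1.
- **Analysis defaults**: FDR target 0.01; conservation threshold 3 of 4
  conditions; candidate cut at the 13.2 percentile; 1000 cross-validation
  iterations (tests use fewer; the acceptance criterion uses 200).

## Numerical choices

- **Exact summation.** `gba_score` uses `math.fsum`, which returns the
  correctly rounded double of the exact sum. Naive left-to-right `sum` of
  the 14 worked-example probabilities yields 0.5886800000000001; `fsum`
  yields 0.58868 exactly and is independent of summation order.
- **Percentile cut guard.** The cut is `int(n · pct / 100 + 1e-9)`. Without
  the guard, binary float round-off can drop the boundary rank (e.g.
  132/1000·100 > 13.2 in floats); with it, 13.2 % of 1017 is exactly 134
  and of 1000 exactly 132.
- **EM details.** Initialization splits the data at the median; convergence
  is declared at a log-likelihood change < 1e-8 (max 1000 iterations);
  component SDs are floored to avoid degenerate spikes. The null component
  is the one with mean closer to 0 (smaller SD on ties). On pure null data
  the fitted components converge to two overlapping halves (weights ≈ 0.5);
  the FDR rule still flags nothing because no posterior is confident.
- **PCIT zero-correlation guard.** A trio containing a zero direct
  correlation has an undefined partial-to-direct ratio and cannot eliminate
  an edge. An off-diagonal |r| = 1 (duplicate expression rows) raises,
  because partial correlations are then undefined.
- **Cross-validation pool.** Held-out disease genes are pooled with the
  full background, including genes whose profile is all-zero (they rank at
  the bottom with score 0). Restricting the pool to scorable genes would
  overstate the difficulty of the task and change the capture curve's
  meaning.
- **Determinism.** Every stochastic step takes an explicit seed; the
  pipeline summary is byte-identical across reruns with equal arguments
  (sorted JSON keys, no timestamps).

## Scope of the synthetic validation and limitations

The generators produce Gaussian expression with independent genes (apart
from the planted effects) and conditionally independent attributes. Passing
the validation demonstrates that the implementation recovers structure it
is designed to detect, under the model it assumes. It does **not**
demonstrate performance on real microarray data, where gene–gene
correlation, batch effects, heavy-tailed noise and annotation bias are all
present; nor does it validate the biological premise that the six
attributes are enriched in the disease genes of any particular disease.

Further limitations:

- The sequential normalization is not a joint ANOVA fit; with strongly
  unbalanced designs the estimated effects differ from least-squares
  estimates.
- The truth table treats the 13 bits as one joint event; with small
  training sets most of the 2^13 state space is unobserved, and scores for
  rare profiles rest on few training genes.
- The capture criterion of the cross-validation acceptance test is the
  mean over three generator replicates (seeds 0, 1, 2) at 200 iterations —
  a Monte-Carlo estimate with residual replicate-to-replicate spread.
- The power-law fit is an OLS diagnostic on binned frequencies, not a
  maximum-likelihood tail estimate; it describes, rather than tests,
  scale-free structure.
- RIF scores are z-standardized within the analyzed TF set, so "extreme"
  is relative to the chosen TF universe.
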