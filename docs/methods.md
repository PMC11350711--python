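# Methods

`cernet` re-implements the downstream analysis of a two-group pig muscle
whole-transcriptome design (high vs low growth rate, four animals per
group) as a tested, seedable pipeline.  This note records the models, the
parameters that matter, and the design decisions taken where the emulated
workflow left the choice open.

## The ceRNA inference chain

The competing-endogenous-RNA (sponge) hypothesis predicts that a lncRNA
sharing miRNA binding with an mRNA relieves that miRNA's repression of the
mRNA.  Its expression signature is: the miRNA anti-correlates with both
partners, and the partners correlate with each other.  The pipeline encodes
this as four filters applied in order:

1. **Differential expression per RNA class** — a feature is DE when
   |log2 fold-change| ≥ 1 (high over low) and p < 0.05.  The
   fold-change bound is read on the log2 scale: a literal linear
   fold-change ≥ 1 would exclude nothing in the upregulated direction.
   p-values are unadjusted, as in the emulated workflow; a
   Benjamini–Hochberg column is emitted for reference but not used for
   calling.
2. **Spearman filtering of predicted miRNA–target pairs** — only edges of a
   user-supplied (or simulated) target map whose endpoints are both DE are
   scored; an edge is kept when SCC < −0.7 (strict, matching "less than").
   Correlations are computed on normalized expression across all samples:
   median-of-ratios-normalized counts for mRNA/lncRNA, counts-per-million
   for miRNA (mature miRNAs carry no length term, so per-million scaling is
   the whole normalization).  Pairs with a constant expression vector have
   undefined ranks and are excluded rather than scored 0.
3. **Candidate ceRNA pairs** — lncRNA–mRNA pairs that share at least one
   passing miRNA and have SCC > 0.9 (strict).  Requiring the shared miRNA
   before the hypergeometric test keeps that test well-defined (overlap
   k ≥ 1) and matches the order of the emulated procedure.
4. **Hypergeometric shared-miRNA test** — for a candidate pair with
   passing-miRNA sets of sizes K (mRNA) and n (lncRNA), overlap k, and
   universe N, the p-value is the exact upper tail P(X ≥ k),
   X ~ Hypergeometric(N, K, n).  The upper tail is the only orientation
   consistent with the sponge hypothesis (the lower tail would reward
   *non*-overlap).  Pairs with p < 0.05 are final.

**The miRNA universe N.** Two definitions are supported.  The default,
`mirna_universe="all_de"`, is all significant DE miRNAs.  The alternative,
`"passing"`, restricts N to miRNAs appearing in correlation-passing pairs.
The passing universe sounds natural but is degenerate when the target map
is sparse: if nearly every passing miRNA belongs to a genuine sponge
triple, N collapses to the number of triples, a singleton overlap scores
p = k·K·n/N ≈ 1/N ≈ 0.05, and real pairs sit exactly on the threshold,
flipping on a single decoy edge.  The DE-miRNA universe is the set the
biological question actually draws from — "of all the miRNAs that changed,
how surprising is this overlap?" — and is stable; it is therefore the
default.

**Network and hubs.**  Final pairs, their witnessing miRNAs and (by
default) direct lncRNA–mRNA edges form an undirected tripartite graph.
Every lncRNA–mRNA edge must be witnessed by a shared miRNA with both
supporting edges present; this invariant is checked on every build and
export.  A node is a *hub* when its degree strictly exceeds the arithmetic
mean degree of the entire network (all classes pooled), so regular graphs
have no hubs.  Edge `regulation` is the DE direction of the regulated,
non-miRNA endpoint (the mRNA's direction for lncRNA–mRNA edges); the
emulated study's figure legend does not pin this down, so it is a
documented convention here.

## The differential-expression stand-in

The named DE packages are deliberately not reproduced.  The test is a
transparent negative-binomial Wald test:

- **Normalization**: median-of-ratios size factors against the
  geometric-mean pseudo-reference over features positive in all samples,
  rescaled to geometric mean 1; upper-quartile fallback (with a warning)
  when no feature is positive everywhere.
- **Effect**: log2((m_high + ½)/(m_low + ½)) on normalized group means; the
  ½ pseudocount avoids infinities.
- **Dispersion**: per-feature method-of-moments estimates
  α̂ = (s² − m)/m² (floored at 10⁻⁸) are far too noisy at n = 4 per group
  to calibrate a Wald test — plugging them in directly makes the z-score a
  t(6) variate in normal clothing and roughly doubles the nominal type-I
  error.  They are therefore stabilized by a mean-expression trend: features
  are ranked by mean, split into up to 20 quantile bins (at least ~100
  features per bin), and each feature receives its bin's mean dispersion.
- **Test**: Wald z of the log-ratio with NB variance
  (1/m_high + α)/n_high + (1/m_low + α)/n_low, two-sided normal p.
  All-zero features report log2fc = 0, p = 1.

Calibration is asserted by simulation, not by output-matching: on null NB
data (10,000 features, 4 vs 4) the fraction of p < 0.05 calls measures
≈ 0.056–0.058 across seeds (band asserted: 0.035–0.065), and a planted
log2 effect of 2 at moderate dispersion is recovered in ≳ 99% of
replicates.

## The synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
every downstream assertion runs under.

- **Design**: two groups of `n_per_group` samples (default 4, as in the
  emulated study); 200 mRNAs, 50 miRNAs, 100 lncRNAs by default.
- **Counts**: gamma-mixed Poisson (negative binomial), baseline means
  log-normal (log-mean 5, log-SD 1.5).  Per-feature dispersions are
  log-normal around `nb_dispersion = 0.3` (spread 0.25) — ordinary
  inter-animal variability for background features.
- **Planted DE**: `frac_de_*` per class (defaults 0.1 / 0.5 / 0.1) extra
  features beyond the triple members get a group-mean log2 ratio of
  ± `lfc_de` (default 2), alternating directions.  The miRNA fraction is
  the largest because the hypergeometric universe is the DE-miRNA set: with
  20 of 50 miRNAs absorbed into triples, a universe of ~45 keeps a
  singleton shared miRNA informative (p ≈ 1/45) even when a decoy edge
  inflates a partner set (p ≈ 2/45 < 0.05), mirroring the real-data regime
  where N comfortably exceeds per-pair target-set sizes.
- **Planted triples**: each triple is driven by a per-sample latent miRNA
  activity a_s = ±lfc_de/2 (group term, sign alternating per triple) plus
  shared jitter of SD `sponge_strength = 0.6` log2 units.  The miRNA mean
  scales as 2^a_s and both partners as 2^−a_s (log-linear link — Spearman
  needs only monotonicity).  Triple members get dispersion
  `triple_dispersion = 0.02` and baselines uniform in [300, 1000]: the
  sponge contract is that latent activity, not counting noise, dominates
  their ranks.  Calibrated once and frozen, the defaults give mean
  SCC(miRNA, partner) ≈ −0.92 and mean SCC(lncRNA, mRNA) ≈ +0.93 averaged
  over 50 seeds at n = 8 — this is the generator contract that makes the
  −0.7/0.9 thresholds meaningful at the study's sample size.
- **Target map**: each triple's miRNA maps to both partners; decoy edges
  are added uniformly at random, `decoy_targets_per_mirna = 2` per miRNA.
- **Phenotypes and qPCR**: per-animal normal draws at configurable group
  means/SDs (defaults plant the published live-weight split 148.38 ± 8.97
  vs 88.75 ± 9.13); Ct tables follow Ct = baseline − log2(expression) +
  N(0, 0.15) per replicate with a flat reference gene, so the 2^−ΔΔCt
  analysis should invert to the planted fold-change.

**What the generator does not emulate**: library-size imbalance beyond what
size factors absorb, batch structure, correlated miRNA families,
many-to-many sponge networks (each planted triple shares exactly one
miRNA), and sequence-level features.  Passing tests therefore demonstrate
the pipeline's correctness and calibration under its stated model, not
performance on real sequencing data.

**Sample sizes in assertions.**  n = 4 per group — the study design — is
kept for all smoke tests and for the generator's SCC contract, but a rank
correlation over 8 points is extremely coarse (the minimum nonzero step is
≈ 0.024, and a single swapped rank can cross 0.9).  End-to-end recovery
assertions therefore run at the generator's documented recovery setting
n_per_group = 12, where the planted-triple recall measures ≈ 0.93–0.95 and
precision 1.0 over 10-seed blocks (asserted: recall ≥ 0.8, precision
≥ 0.9).

## Phenotype statistics

Printed summaries (mean ± SD, n) are first-class inputs: the two-sample t
(pooled, df = n₁+n₂−2, or Welch–Satterthwaite) is computed directly from
them, and significance letters follow the livestock-table convention
(different lowercase ⇔ p < 0.05, different uppercase ⇔ p < 0.01, larger
mean gets the first letter).  With equal n the two variants share the t
statistic and differ only in df.  For raw per-animal data a Brown–Forsythe
(median-centered Levene) gate at p ≥ 0.05 selects pooled vs Welch, and a
classical one-way ANOVA is provided (F = t² for two groups).  Degenerate
inputs are defined, not special-cased away: both SDs zero gives p = 1 for
equal means and p = 0 (with a warning) otherwise.

Five of the 27 published summary rows cannot be reproduced from their own
printed numbers under any t variant (letters claiming significance at
computed p ≈ 0.15–0.26, or SDs so small that a claimed non-significant
difference computes to p ≈ 10⁻¹⁰).  The module computes from what is
printed and flags |t| > 50 as suspicious (those SDs are likely SEs or
typos); the reproducible 22 rows are pinned in the unit suite, and the
all-rows check is kept as a strict acceptance test that documents the
discrepancy rather than hiding it.

## Enrichment and qPCR

Enrichment is local hypergeometric over-representation against a
user-supplied term table, sharing the exact kernel with the ceRNA test
(one implementation, two callers, cross-asserted).  The universe defaults
to all annotated genes — the emulated web service's universe is unknowable
— and is configurable.  The qPCR module averages replicate Ct values,
subtracts the reference gene (GAPDH for mRNA/lncRNA, U6 for miRNA assays),
calibrates on the low group so RQ > 1 in the high group reads as
upregulation (matching the DE log2fc sign), and compares groups with a
t-test on log2(RQ) by default (variance stabilization; raw-RQ retained).
Plate offsets cancel through the reference; this invariance is asserted.

## Numerical conventions

Strict inequalities wherever the emulated thresholds say "less/greater
than" (−0.7, 0.9, and every p < 0.05/0.01 boundary); fold-change boundary
|log2fc| ≥ 1 inclusive.  ceRNA results are ordered by ascending p, then
descending SCC, then lexicographic ids, so outputs are deterministic under
ties.  All randomness flows from explicit integer seeds through
`numpy.random.Generator`; phenotype and qPCR simulations use independent
streams derived from the same seed.
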