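# Methods

`pairlearn` learns many-to-many associations between genetic variants (SNPs)
and continuous imaging-derived phenotypes (IDPs) with a contrastive
dual-encoder, using diseases as mediators to define the supervision pairs.
This note records the model, its assumptions, the statistical machinery
around it, and the design decisions taken where more than one reasonable
choice existed.

## Pair supervision by disease mediation

A supervision pair (IDP *i*, SNP *s*) exists when both entities are linked to
the same disease: the SNP through an association catalog (with association
p-value), the IDP through a phenome-wide scan. The scan fits, per
(IDP, disease), a logistic regression of the disease indicator on the
standardized IDP plus covariates (age, sex, smoking, height, BMI, genetic
PCs, all standardized) and tests the IDP coefficient with a Wald test; an
IDP maps to a disease when p < α / (n_IDPs × n_diseases) with α = 0.05
(Bonferroni at the family level — the scan threshold is configurable because
no canonical value exists). Non-converged or separated fits are recorded
with p = 1 and flagged rather than dropped.

Each surviving (IDP, disease) × (SNP, disease) combination is expanded to
one record per sample; duplicates arising from multiple mediators keep the
mediator with the smallest catalog p. Records are split 70/20/10 into
train/validation/test by shuffling records (`by_pair`); because one sample's
records can then appear on both sides of the split, a `by_sample` mode that
assigns whole samples to splits is provided for leakage-sensitive analyses.
Top-SNP selection keeps the ceil(percent% of unique SNPs) with the smallest
catalog p (a SNP's strength across diseases is its minimum p; ties break
lexically).

The mediation assumption — related to the same disease implies related to
each other — is deliberately weak: many expanded pairs are spurious, and the
point of the method is that consistently retrieved pairs are the real ones.

## Tokenization

*IDPs.* Values are encoded relative to the training distribution with a
piecewise linear encoding (PLE): per IDP, bin boundaries are the empirical
quantiles 0, 1/T, …, 1 of the training-split values (T = 10 by default;
quantile, not equal-width, because the encoding is meant to be rank-based).
A value maps to a vector in [0,1]^T — ones for bins entirely below it, one
fractional interpolated entry, zeros after — so encoding is componentwise
monotone. Values at or below the lowest boundary give all zeros, at or
above the highest all ones (test values may leave the training range).
Duplicate quantiles from heavy ties are collapsed with a warning; a constant
IDP is an error. Missing values are mean-imputed with the training mean.
Boundaries are fit on the training split only and never updated afterwards.

*SNPs.* A genotype call is a pair of integer tokens: the SNP identifier
(acting as a positional encoding of genomic identity) and the mutation
status from the six-code alphabet {hom_ref, het, hom_alt, insertion,
deletion, missing}. Any call carrying an alt allele at an indel site is
coded insertion/deletion by alt-vs-ref length; SNV sites code het/hom_alt by
alt count. Vocabularies are frozen after fitting; unseen identifiers raise
instead of mapping to an unknown token.

## Dual encoder and contrastive objective

Each modality has its own transformer encoder (2 layers, d_model = 64,
4 heads, feed-forward width 64 by default — the tuned configuration; a
32-wide feed-forward is available). The SNP branch concatenates a 32-dim
SNP-ID embedding with a 32-dim status embedding; the IDP branch concatenates
a 32-dim IDP-ID embedding with a linear map of the PLE vector. Each
concatenation is a single-token sequence through its encoder stack
(pre-norm residual blocks; for one token, self-attention reduces to its
value/output projections — implemented as an exact fast path, with the
general multi-head attention retained and gradient-checked for longer
sequences). Projection matrices W_s, W_i map encoder outputs to a joint
d_e = 32 space; rows are L2-normalized:

    S_e = S_f W_s / ||S_f W_s||,   I_e = I_f W_i / ||I_f W_i||

Within a batch of b records the logits are the b × b cosine similarities
scaled by a learnable temperature exp(τ) (initialized to 1/0.07 as in CLIP
and clamped to [1/100, 100]; a fixed τ = 1 mode exists). The loss is the
symmetric cross-entropy — the average of row-wise and column-wise
cross-entropies with diagonal targets; it equals ln b at indifference.

Optimization is Adam with decoupled weight decay (applied to weight
matrices only, never biases, gains or embeddings), linear learning-rate
warmup (first step lr/warmup_steps) followed by a constant rate; defaults
lr = 0.0033, 236 warmup steps, weight decay 0.0015, batch 64, at most 50
epochs with early stopping after 10 epochs without validation improvement.
The best-validation epoch's weights are kept. All layers are implemented
directly on numpy with hand-derived gradients; every gradient is verified
against central finite differences in the test suite, and training is
bit-reproducible from the run seed on one device.

## Two retrieval accuracies

Evaluation logs, per test record, whether its row's argmax hit its own
column. Two notions of "correct" are reported:

* **positional** — the argmax must be the diagonal entry (ties break to the
  lowest index and only the diagonal counts). With small vocabularies a
  batch of 64 necessarily repeats SNP token pairs (20 SNPs × ~3 observed
  statuses ≈ 35 expected distinct tokens per batch); repeated rows are
  identical and share one argmax, so positional accuracy is bounded by
  E[#distinct row tokens]/b for *any* model. It is the validation metric
  and the input to the pair statistics, where the bound is harmless because
  it depresses all pairs alike.
* **identity-matched** — the argmax column must carry the record's IDP
  identity. This is the scale on which "every pair retrieved correctly" is
  observable, and the package's headline pair-learning accuracy: on the
  planted-bijection cohort it reaches 100% while positional accuracy sits
  at its collision ceiling (~0.26 at batch 64).

## Per-pair significance

Collating the positional flags gives per-pair counts (n_correct, n_seen).
Each pair is tested against the null that all pairs share the model's
overall accuracy p̂ = Σ n_correct / Σ n_seen with a 2-cell goodness-of-fit
chi-square (df = 1) on (correct, incorrect) counts; the upper tail of
χ²(1) gives p. The statistic is also reported scaled by the number of
observations (the global total by default, the pair's own n_seen
optionally) because absolute frequencies differ by orders of magnitude
between pairs. Adjustment is Benjamini–Hochberg (Bonferroni optionally).
Degenerate nulls (overall accuracy 0 or 1) are flagged with p = 1. The
chi-square is two-sided, so each pair carries an `enriched` flag
(observed > expected); a *learned* pair is significant **and** enriched —
significant depletion (typical of decoys sharing a batch with well-learned
pairs) is not discovery. Under a uniform random-retrieval null the pooled
p-values are uniform (KS-tested in the suite over 200 simulated logs).

## Genotype QC

Samples with more than 10% missing calls are removed first, then SNPs with
missingness > 5%, minor allele frequency < 0.05 (from dosages, missing
ignored), or Hardy–Weinberg p < 1e-16 (exact test when fewer than 1000
genotyped samples, 1-df chi-square otherwise; the exact test sums
conditional heterozygote-count probabilities no larger than the observed
one). Because removing SNPs changes sample missing fractions and vice
versa, the sample→SNP round iterates to a fixed point, which makes the
filter idempotent. Every removal is reported with its reason and value;
heterozygosity-variance and relatedness filters are noted as not applied
(no defensible default thresholds). MAF/HWE are always computed on the
currently retained samples.

## Synthetic cohorts

The generator makes the mediation assumption literally true: dosages are
binomial(2, MAF) i.i.d. across samples and SNPs; each disease is Bernoulli
with a logistic risk in its cataloged SNPs' centred dosages (weight
proportional to −log10 of the catalog p, so catalog order reflects real
link strength; the intercept is calibrated by root-finding so mean risk
equals the target prevalence); each IDP is Σ β·dosage over its planted
SNPs, plus disease shifts, optional age/sex terms and Gaussian noise.
Two ready-made designs:

* `planted_bijection_spec` — one true SNP per IDP, each pair under its own
  mediating disease plus one cataloged β = 0 decoy SNP, so pair expansion
  yields a clean dictionary (every SNP has exactly one partner IDP). This is
  the retrieval test-bed: 2000 samples, 20 SNPs at MAF 0.3, 10 IDPs, β = 2
  per alt allele, noise SD 0.1.
* `single_disease_spec` — one disease mediates everything, pair expansion is
  the full cross product, and the planted diagonal hides among β = 0
  decoys. This is the significance test-bed.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population stratification, non-Gaussian phenotype noise, realistic
inter-IDP covariance, genotyping batch effects. Passing tests therefore
show that the pipeline recovers planted structure under its own modelling
assumptions, not that it would perform identically on biobank data.

## Downstream tasks

Per-sample entity embeddings are extracted in eval mode (frozen encoders;
a checksum guard asserts the weights never change during head training):
each vocabulary SNP's (ID, status) pair and each IDP's (ID, PLE) pair is
encoded and projected; blocks are concatenated SNP-block-first in
vocabulary order into one fused vector per sample.

* *Disease classification* — one hidden layer (width 64, ReLU, dropout
  0.2) on the fused vector with covariates appended; inverse-class-frequency
  loss weights; stratified 80/20 sample split; AUC reported.
* *Risk-score regression* — same head shape, MSE loss on the z-scored
  target (predictions mapped back); the train split is the disease's cases
  plus an equal number of controls, evaluation on the remaining, completely
  unseen controls; R² = 1 − SS_res/SS_tot (can be negative). Cross-disorder
  evaluation reuses the trained head verbatim on another disease's
  evaluation split.
* *CCA comparison* — canonical correlations between the vectorized SNP-side
  and IDP-side embeddings of samples unseen in contrastive training,
  against CCA on raw dosages/IDPs on the same samples, covariates
  residualized out and views standardized. Note that with embedding
  dimension × entities exceeding the held-out sample count the embedded CCA
  saturates at 1.0 partly by rank; the comparison is reported exactly as
  such, mirroring the original experimental design.
* *Baselines* — CCA-fused SVM (first 10 canonical variates of both raw
  views, RBF SVM) and a shallow MLP on concatenated raw features.
* *Latent clustering* — k = 5 sampled encodings per entity, reduced to 2-D
  (UMAP by default, PCA optionally), K-means (K = 8 default) per modality;
  an entity's label is the majority cluster of its points.

## Problem sizes used by the test and acceptance runs

The packaged experiments run at desk scale on one CPU: the retrieval
experiment uses the 2000(+400 held-out)-sample bijection cohort with the
full-size encoder (~1 min). The significance power/specificity study uses
the bijection design at 1500 samples with 6 IDPs (6 planted + 6 decoy
dictionary pairs), trained for the full 50 epochs with best-epoch selection
on validation retrieval measured at batch 16, and evaluated in batches of
16 over 4 reshuffled passes of the test records, repeated over 10 seeds
(~90 s each). Two evaluation-protocol choices deserve a note: the in-batch
chance rate is 1/b, so small *evaluation* batches spread per-pair
frequencies over a wider range and sharpen the chi-square contrast without
touching the training protocol; and because each reshuffled pass redraws
every record's in-batch competitors, repeated passes multiply the per-pair
observation counts cheaply (successes are independent across passes only
conditionally on the record, so counts are mildly overdispersed — decoys
are protected by the enrichment direction, which they sit firmly below).
Null calibration uses 200 simulated logs of 40 pairs. These sizes are the
package's chosen operating points for routine verification; the library
itself has no scale-specific logic.

## Known limitations

* In the all-cross (single-disease) regime the value-matching signal is
  weak — only a fraction of records pair a SNP with its true IDP — and
  discovery of planted pairs by the optimizer is sequential and slow; a
  partially converged model can hold *spurious* consistent preferences that
  the per-pair test then flags, exactly the spurious-association behaviour
  expected of the method. This regime is exposed as the `single_disease`
  design of the significance experiment but is not part of routine
  verification. Even in the easier bijection regime, discovery of an
  individual pair can occasionally stall within the epoch budget
  (observed in roughly one seed in ten), which is why the power criterion
  is stated over repeated seeds.
* Positional in-batch accuracy is structurally bounded below 100% whenever
  the batch size exceeds the number of distinct SNP tokens; comparisons
  across batch sizes or vocabularies must use the identity-matched scale.
* In-batch duplicate collisions are treated as CLIP treats them (only the
  diagonal is correct); with small vocabularies this is a meaningful
  approximation, quantified above.
* The uniform-accuracy chi-square null ignores between-pair heterogeneity
  in batch composition; its calibration is verified empirically under the
  random-retrieval null.
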