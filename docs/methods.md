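# Methods

## Problem and model

The task is binary subtype classification of tumor samples — adenocarcinoma
(AD, positive class; LUAD within the lung) vs. squamous cell carcinoma
(SCC/LUSC) — from a sparse binary gene-mutation matrix, with a dense
expression z-score matrix available at training time only as a source of
regularization. The scientific question the analysis probes is not raw
accuracy but *calibrated selectivity*: mutation profiles are ambiguous for
a substantial fraction of tumors (some carry driver mutations of both
subtypes), so the model must say which predictions to trust.

All three model variants share one multilayer perceptron: encoder
`input → 256 → 128 → 64` with ReLU activations; each prediction head
applies dropout (rate 0.2) to the 64-dim latent and feeds one sigmoid
output neuron. With two heads, head 0 classifies AD vs. SCC among lung
samples only (the NSCLC task that is actually evaluated) and head 1
classifies AD vs. SCC across all tissues; the pan-tissue head lets non-lung
AD/SCC samples regularize the encoder. The training loss is

```
L = BCE_pan(all samples) + BCE_lung(lung samples) [+ λ · A]
A = mean_i Σ_k (z_ik^mut − z_ik^expr)²
```

where each BCE term is averaged over its own support (a batch with no lung
samples contributes only the pan term), and `A` is the latent-alignment
penalty of the expression-aware genomic model against a frozen, pre-trained
expression model. The alignment convention — sum over the 64 latent
coordinates, mean over samples — is fixed so that tests can assert exact
values; "L2 between latent representations" is otherwise ambiguous between
sum and mean scalings, which only rescales λ.

Expression-aware training has two phases: alignment-only for the first 30
epochs (`warmup_epochs`), then the task losses are switched *on top of* the
alignment term (addition, not replacement — treating the switch-on as a
replacement would discard the transfer signal mid-run). Teacher latents are
precomputed once; the teacher is frozen throughout. The early-stopping
clock starts when the task loss switches on. With λ = 0 and no warmup the
code path is identical to plain task training, so the expression-aware
trainer reduces bit-for-bit to the baseline genomic trainer at a fixed
seed; this reduction is asserted in the test suite.

### Training parameters

| parameter | default | notes |
|---|---|---|
| hidden sizes | 256/128/64 | latent = last hidden layer |
| dropout | 0.2 | heads only, training mode only |
| optimizer | Adam, lr 1e-4 | β = (0.9, 0.999), ε = 1e-8 |
| batch size | 64 | class-balanced sampling with replacement, epoch size = training-set size |
| early stopping | patience 20 | on validation loss, best checkpoint restored |
| max epochs | 500 (library default); 120 in the reference study | patience binds first in practice; the cap keeps a 100-model study in minutes |
| warmup epochs | 30 | alignment-only phase |
| λ (alignment weight) | 1.0 | unstated in the source analysis; sensitivity: λ→0 recovers the baseline genomic model exactly, λ ≫ 1 (tested at 50) measurably shrinks student–teacher latent distance but does not raise NSCLC AUC — consistent with the alignment improving the manifold, not the decision boundary |

Per-model seeds are derived deterministically from the base seed, the fold
index and the member index, so any single member is reproducible in
isolation. All inference is dropout-free and deterministic.

## Cross-validation and the ensemble

Stratified k-fold (default 10; 5 in the desk-scale study) over NSCLC
samples only; non-NSCLC samples never enter a test fold but join every
fold's 80/20 train/validation split (both splits stratified by subtype).
Within a fold, one expression teacher is trained on the fold's training
split; the training set is then bootstrapped M times (with replacement,
same size), one expression-aware student per bootstrap, validation shared.
One teacher per fold (not per bootstrap) keeps the cost at M students + 1
teacher and matches the two-phase schedule being described once per fold.

Ensemble outputs per sample: majority class (vote threshold 0.5 on the
sigmoid output), majority size `u ∈ [0.5, 1]` as the confidence estimate,
and the aggregated score = mean score of exactly the majority-voting
members. An exact 50/50 tie is resolved by the mean score against 0.5, and
to LUAD at exactly 0.5 — an arbitrary but deterministic rule needed for
even M. The aggregated score always lies on the majority's side of 0.5 by
construction (asserted property).

## ROC conventions

TPR/FPR at threshold t count calls `s ≥ t` (ties are positive calls),
weighted when sample weights are given: both numerator and denominator of
each rate take the weights. Unweighted trapezoidal AUC over the unique-
score operating points equals the Mann–Whitney pairwise statistic with
ties counted half; the weighted version equals the weighted pairwise
statistic (both asserted against brute-force oracles). Fold aggregation
re-evaluates every fold's step curve exactly on the union of all folds'
thresholds, averages per threshold, and integrates the mean curve; the SD
across folds accompanies each operating point, and the reported `auc_sd`
is the SD of the individual fold AUCs. Rejection analysis retains samples
with `u ≥ τ`, re-aggregates the ROC per fold (a fold reduced to one class
or fewer than two samples is skipped with a warning) and reports the
fraction rejected; τ = 0.5 reproduces the unrejected summary bit-exactly.

## KernelSHAP

Attributions target the ensemble's two aggregated functions — the
aggregated prediction score (LUAD axis) and the majority size — not
individual members. For an explained sample, coalitions of present/absent
features are built; absent features are imputed from each background row
in turn and the target averaged over the background. When the coalition
budget covers all 2^M − 2 non-trivial coalitions, they are enumerated with
exact Shapley-kernel weights, which makes the weighted-least-squares solve
equal to exact Shapley values of the background-imputed value function
(asserted to 1e-6 against exhaustive enumeration at 5 and 8 features).
Otherwise coalition sizes are drawn from the kernel's size distribution
and subsets uniformly within a size, with uniform regression weights (the
sampling distribution already carries the kernel). The sum constraint
(local accuracy: attributions sum to f(x) − E[f]) is enforced exactly by
eliminating one coefficient. Background: a class-balanced random subsample
of the fold's training samples (default 50 rows; 12 in the reference study),
coalition budget default 2·n_genes + 2048 (1024 in the study), per-fold
estimation merged across folds with sample-count-weighted baseline
averaging. Global gene importance = mean |attribution| across explained
samples.

## UMAP comparison

UMAP (n_neighbors 15, min_dist 0.1, Euclidean, fixed random_state) is fit
on the expression encoder's latents for the test samples; genomic latents
are passed through the *fitted* transform so both manifolds live in the
same coordinates. Transforming the training matrix itself returns the
fitted embedding directly (umap-learn's stochastic transform would
otherwise return a near- but not bit-identical embedding for the same
points, which would violate the intended fit–transform consistency).

## Synthetic cohort generator

The generator is a statistical stand-in — the source cohorts provide no
generative model, so its distributions are deliberately minimal:

* Four (histology × tissue) cells over {lung, other}, 300 samples each by
  default: 600 NSCLC + 600 non-lung samples, 200 genes.
* Mutations are independent Bernoulli given histology: 4 AD-marking and 4
  SCC-marking driver genes at 25% frequency in the marked histology vs. 3%
  in the other (chosen to land mutation-only classification in the
  0.8–0.9 AUC range, the sparse-signal regime of interest), background
  rate 2% elsewhere. Driver columns are named after the eight canonical
  NSCLC drivers (KRAS/EGFR/BRAF/STK11, CDKN2A/NFE2L2/PIK3CA/PTEN) so the
  driver-subgroup analysis runs unchanged.
* A mixed-driver subpopulation: 15% of samples (exactly
  `round(0.15·n)`, chosen uniformly) get one driver of each histology
  forced to 1, creating genuinely conflicting profiles.
* Expression: standard normal, except 20 informative genes (disjoint from
  drivers by default) shifted ±effect/2 by histology with effect 2.0 —
  enough for near-perfect linear separability, mirroring the transcriptomic
  regime.
* Optional exponential progression-free-survival times per histology with
  uniform-fraction censoring; carried as annotations only (survival
  estimation is out of scope).

What the generator does *not* emulate: mutational signatures and
co-occurrence structure beyond the mixed-driver mechanism, copy number,
tumor purity, panel coverage, expression covariance between genes, and
batch effects. Passing tests therefore demonstrate that the machinery
recovers planted structure under the stated assumptions — not that the
real-data AUCs transfer.

## Desk-scale study and what it reproduces

The reference study (`study.py`, also behind `scripts/acceptance.py`) uses
5 folds × 20 members, max 120 epochs, SHAP over 4 explained samples per
fold with 1024 coalitions and background 12 — sizes chosen so the complete
analysis runs in minutes on one CPU. At this scale the qualitative
patterns of the full-size analysis reproduce: the expression model
dominates the mutation-based models; correct predictions carry larger
majority sizes than errors; confidence-weighting adds ~0.02 AUC; rejecting
at u ≥ 0.75 raises AUC while rejecting ~20% of samples; planted drivers
occupy the top SHAP ranks; mixed-driver samples show intermediate
confidence (below either single-driver subgroup, above the 0.5 floor).

Known limitation: at the harshest rejection threshold (u ≥ 0.95, i.e. at
least 19 of 20 members agreeing) the retained set shrinks to ~35–45
samples per fold, dominated by extreme aggregated scores. A handful of
unanimous-but-wrong mixed-driver samples then carries large rank weight,
and the AUC of the retained set can dip below the u ≥ 0.75 value even
though accuracy keeps rising — strict AUC monotonicity in the rejection
threshold is an empirical tendency of large ensembles and cohorts, not a
guarantee of the method, and with 20 members the majority size is
quantized to 1/20 so the 0.95 cut is effectively a unanimity filter. The
mid-threshold regime, where the selective-prediction claim lives, is
robust across seeds.

## Numerical choices and degenerate inputs

* Sigmoid computed in the numerically stable split form; BCE scores
  clipped at 1e-7 for the loss value (gradients use the exact
  `score − label` form).
* Encoder weights He-initialized, heads at 1/√fan-in, biases zero.
* Zero-variance genes are dropped (with a warning) by fallback z-scoring;
  pass-through mode is the default since cBioPortal archives ship z-scores.
* Sample SD (ddof = 1) in fallback z-scoring and in the score-variance
  uncertainty.
* Mutation records with consequence classes outside the configured
  non-synonymous set (default: the standard MAF nonsynonymous classes) are
  ignored; records for unknown samples/genes are skipped and counted.
* Empty confusion categories yield empty groups, not errors; a constant
  attribution target yields all-zero attributions.
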