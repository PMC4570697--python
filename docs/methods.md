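# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limitations of `synapred`.

## Classification model

Each gene *i* is represented by its normalized temporal profile
x_i ∈ [0,1]²⁴ (24 embryo/larva/pupa samples divided by their maximum; the
six adult samples are never part of the feature vector — they feed only the
sex-bias training criterion, on raw FPKM). Three non-parametric classifiers
estimate P(y_i = 1 | x_i):

* **k-NN** — p = (positive labels among the k = 25 Euclidean nearest
  training profiles)/k. Implemented directly (`cdist` + stable argsort)
  so that exact distance ties at the k-th rank resolve deterministically
  by gene id; probabilities are multiples of 1/k.
* **Random forest** — B = 500 fully grown trees, m = 4 candidate variables
  per split; p is the fraction of trees voting positive (a vote fraction,
  not an average of leaf frequencies).
* **RBF-SVM** — decision values mapped to probabilities by a Platt sigmoid
  fitted on 5-fold cross-validated decision values. C and γ are chosen by
  a 10-fold cross-validated grid search over
  C ∈ {0.5, 1, 2.2, 5, 10} × γ ∈ {0.005, 0.01, 0.02, 0.05, 0.1}; ties go
  to the smaller C, then the smaller γ. The grid is log-spaced around the
  region where RBF-SVMs on 24-dimensional [0,1] profiles typically land
  and is configurable.

A gene is called synaptic when p *strictly exceeds* the threshold
("must exceed"): boundary genes are excluded everywhere. No class
weighting or resampling counteracts the ~1:4.3 positive:negative
imbalance; the cross-validation folds are stratified by label (with 92
positives, unstratified 10-folds occasionally degenerate). The fold split,
forest and any resampling all derive from one explicit seed; a rerun with
the same seed is byte-identical. AUC is reported from the pooled
out-of-fold probabilities (per-fold values are kept in the report as
well).

## Training-set construction

Negatives are the union of the two criterion sets (a gene meeting both is
counted once; per-criterion provenance is retained). Curated positives
outrank the heuristics: a positive that also meets a negative criterion
stays positive and the conflict is logged. Positives missing from the
expressed set are dropped with a warning. The classification set is the
expressed set minus the training set, asserted disjoint on every run.
Labels never read the 24-sample profiles, so CV performance is not
label-leakage.

## Enrichment

For a catalogue of n genes within a background of N, a term with B
background members and b catalogue members has enrichment (b/n)/(B/N) and
p = P[X ≥ b], X ~ Hypergeometric(N, B, n) (scipy), with BH-FDR q-values
across all terms tested for that catalogue (statsmodels). The background
is always the classified gene universe — the expressed genes minus the
training set — so training genes cannot drive an enrichment. Term
membership is recomputed inside the background before any arithmetic.
Genes carrying no annotation at all still count in N (the plain reading of
the formula); a stricter annotated-only universe can be obtained by
passing a reduced background.

## Tissue specificity and homolog overlap

A gene has tissue-specific differential expression (GTSDE) when its
expression is ≥ `high_min` in exactly one of five larval tissues (CNS,
salivary gland, fat body, digestive system, carcass) and ≤ `low_max` in
the four others, making the per-tissue lists disjoint by construction.
The source bins for "moderate" and "very low" expression are categorical,
not numeric; the defaults `high_min` = 4 and `low_max` = 1
(expression-table units) are the package's own calibration and both are
exposed.

The homolog evaluation counts catalogue genes with ≥ 1 human homolog
carrying a synapse annotation (gene-level: several synaptic homologs count
once). Its null draws random gene lists of the catalogue's pre-exclusion
size from the classified background, removes genes annotated to any
synapse-related term *after* drawing (mirroring the exclusion applied to
the real catalogue), and counts synaptic homologs; 100 seeded repetitions
by default, reported with mean, central 95 % interval and any percentile.

## Synthetic data-generating process

The generator emulates the statistical structure the analysis assumes:

* **Synaptic genes** (92 curated positives + 800 hidden synaptic genes
  left in the classification set, the analogue of the to-be-discovered
  catalogue) follow the two-wave template: FPKM `wave_high` = 10 in stage
  samples 7–12 and 19–24, `trough_low` = 1 elsewhere, moderate adult
  expression.
* **Negatives**: 352 CNS-depleted genes (tissue table built so their
  CNS/whole-body ratio is < 0.05 and nobody else's is) and 45 extreme
  sex-bias genes (one sex exactly 0 in all three adult samples, the other
  > 25 FPKM in at least one), both with heterogeneous non-wave stage
  profiles.
* **Background** (12,000 genes): a mixture of flat, monotone and
  single-peak templates plus a graded kind (40 % of draws) blending a flat
  profile with the two-wave template. Blend weights follow a modular
  mixture — 75 % weakly coupled (w ∈ [0, 0.55]), 5 % partially coupled
  (w ∈ [0.55, 0.9]), 20 % strongly co-regulated module members
  (w ∈ [0.9, 1]) — because co-expression in a developmental transcriptome
  is modular: a sizable module shares the synaptogenesis timing without
  being synaptic, which is exactly what inflates low-threshold catalogues
  and makes threshold escalation informative. Planted negatives draw the
  same mixture capped at w ≤ 0.5: CNS-depleted or sex-biased genes can be
  mildly wave-modulated but are never module members.
* **Adult-only genes** (200): exactly zero in all 24 stage samples,
  positive in ≥ 1 adult sample; they must be removed by the expression
  filter.
* **Noise**: multiplicative log-normal with σ = 0.4 on every FPKM value
  (≈ 40 % coefficient of variation, typical of bulk RNA-seq biological
  replicates). FPKM are non-negative and right-skewed, which a
  multiplicative model respects; zeros stay exactly zero. At σ = 0 the
  two training classes are exactly separable (verified by a linear SVM
  reaching zero training error and by zero CV error for all three
  models).
* **Annotations**: one planted `synapse_like` term containing 50 % of the
  synaptic genes plus background genes at a 2 % base rate, among 50 GMT
  terms (the rest uniform random); the planted term doubles as the
  synapse-related exclusion list for the final catalogue.
* **Homology**: each gene has a human homolog with probability 0.68
  (≈ the fraction of catalogue genes with a human homolog in fly–human
  maps); the homolog carries a synapse annotation with probability 0.11
  for synaptic genes versus 0.025 for everything else — the elevated rate
  is the planted cross-species signal the overlap evaluation must detect.

All sub-generators derive independent streams from one root seed;
identical config + seed reproduces every artifact bit-for-bit.

### What the generator does not emulate

Read counts and sequencing error; between-sample normalization artifacts;
correlated noise across samples or co-expression beyond the single wave
module; realistic GO term hierarchy (terms are flat sets, no true-path
propagation); orthology complexities (paralogy, many-to-many maps beyond
an occasional second homolog). Passing tests therefore demonstrate that
the pipeline recovers planted structure under realistic marginal noise,
not that it would meet the same numbers on any real transcriptome.

## Numerical and design choices

* Thresholds are applied with strict `>`; catalogue series over
  thresholds are therefore nested, and the sweep asserts monotone
  non-increasing sizes on every run.
* Normalization maxima are taken over the 24 stage columns only; ties at
  the maximum need no tie-break (division by the value).
* Degenerate inputs fail loudly: all-zero stage profiles cannot be
  normalized, k larger than the training set, empty SVM grids, thresholds
  out of order and draw sizes exceeding the background all raise typed
  errors. A missing homology map skips that stage with a log message
  rather than aborting the run.
* Empty catalogues yield missing (NaN) enrichment and tissue proportions
  rather than zeros.
* The tissue-proportion trend is evaluated as under-representation
  against the classification-set baseline plus a rising CNS share across
  the sweep: individual non-CNS shares rest on 2–6-gene intersections and
  can wiggle by a fraction of a percent between adjacent thresholds, so
  per-step monotonicity of every tissue series is not a well-posed claim
  at this problem size.
* Problem sizes in the test suite: unit tests run a miniature study
  (~500–1,500 genes); the end-to-end suite and the acceptance script run
  the full default study (13,489 genes, 489 training, 12,800 classified),
  which completes in well under a minute on one CPU.

## Known limitations

The final-catalogue homolog contrast is diluted relative to the
consensus-catalogue contrast because the planted annotation covers half
the hidden synaptic genes and the exclusion step removes them; the
resampling comparison is therefore reported for both catalogues. The
SVM grid is coarse by design (25 points); refining it changes (C, γ) but
not the CV error plateau on separable-to-near-separable data. k-NN
probabilities saturate at |positives|/k when the positive class is
smaller than k, which matters for miniature configurations but not for
the default 92-positive study.
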