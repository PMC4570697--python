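# synapred

Prediction of putative **synaptic genes** from a whole-body developmental
transcriptome by a three-classifier consensus ensemble.

## The problem

Assembly and function of neuronal synapses require the coordinated
expression of a large, mostly unidentified set of genes. In *Drosophila
melanogaster* the life cycle contains two waves of massive synaptogenesis —
the second half of embryogenesis and the pupal stage, when the adult brain
is wired — separated by a larval period of synapse disassembly. Genes
required at the synaptic active zone are therefore expected to carry a
distinctive **two-wave temporal expression signature**: elevated FPKM in
stage samples 7–12 and 19–24 of a 24-sample embryo/larva/pupa series, with
a trough in samples 13–18.

`synapred` is for computational biologists who want to exploit that
signature: it learns it from a curated training set and produces ranked
catalogues of candidate synaptic genes, reducing the number of genes that
must be tested by hypothesis-driven experimentation.

## The method

1. **Preprocessing.** Keep genes with transcript level > 0 in at least one
   of the 24 pre-adult samples; each gene's feature vector is
   x_i = {x_i^j : j = 1..24}, its stage series divided by its maximum, so
   profile *shape* rather than absolute abundance drives classification.
2. **Training set.** Positives: a curated list of genes with unequivocal
   active-zone function (92 by default). Negatives: genes satisfying at
   least one of two biology-only criteria — CNS/whole-body expression
   ratio < 0.05 at the third larval instar, or extreme sex bias in adults
   (0 FPKM in one sex, > 25 FPKM in the other). Neither criterion reads
   the temporal profiles, so labels and features stay independent.
3. **Classifiers.** Three estimators of P(y_i = 1 | x_i): k-NN (k = 25,
   Euclidean), random forest (B = 500 trees, m = 4 variables per split),
   and an RBF-kernel SVM with Platt-calibrated probabilities and (C, γ)
   tuned by cross-validated grid search. Generalization error is estimated
   by stratified 10-fold CV; AUC from pooled out-of-fold probabilities.
4. **Consensus and threshold escalation.** A gene enters a catalogue when
   its probability strictly exceeds a threshold t ∈ {0.5, …, 0.9}; the
   consensus catalogue is the intersection of the three per-model
   catalogues. The final catalogue removes genes already carrying a
   synapse-related annotation, leaving novel candidates.
5. **Evaluation.** Catalogues are characterized by (a) gene-set enrichment
   against the classified background, enrichment = (b/n)/(B/N) with a
   hypergeometric upper-tail p-value and Benjamini–Hochberg q-value
   (cutoffs p < 10⁻⁴, q < 10⁻³); (b) the proportion of tissue-specific
   genes per tissue (CNS vs synapse-poor tissues); and (c) the count of
   catalogue genes with a human homolog already annotated as synaptic,
   against a resampling null of random same-size gene lists.

A bundled synthetic-data generator emulates all five inputs — expression
matrix, positive list, tissue table, GMT annotations, homology map — with
the two-wave signal, planted negatives, adult-only genes, a graded
continuum of wave-coupled background genes and a planted synapse-like
annotation term, so the full pipeline runs and is tested without any
external download.

## Worked example

Run the whole pipeline on the default synthetic study (13,489 genes,
92/397 training set):

```bash
synapred run-all --seed 1 --out out
```

prints the stage-by-stage gene accounting

```json
{
  "total": 13489,
  "excluded_no_stage_expression": 200,
  "expressed": 13289,
  "positives": 92,
  "negatives": 397,
  "training": 489,
  "classified": 12800,
  "consensus_top": 910,
  "final_catalogue": 621,
  "excluded_annotated": 289
}
```

and writes all artifacts under `out/` (normalized profiles, probability
table, sweep table, catalogues, enrichment and tissue-proportion tables,
`manifest.json`). In this run the manifest reports, per model, the 10-fold
CV mean error and pooled AUC — k-NN 0.61 % / 1.000, RF 0.0 % / 1.000,
SVM 0.0 % / 1.000 — a k-NN coincidence with RF and SVM of 83.6 % and
87.5 % at the 0.5 rule, consensus catalogues shrinking 1768 → 910 as the
threshold rises 0.5 → 0.9, the planted synapse-like term's enrichment
growing 4.9 → 6.5 over the same sweep, the CNS share of tissue-specific
catalogue genes growing 90.9 % → 92.8 %, and 16 final-catalogue genes with
a synaptic human homolog against a random-list null mean of 16.5 (the
pre-exclusion consensus catalogue scores 38 against a null 99th percentile
of 26). Interpretation: the ensemble recovers the planted two-wave genes
almost perfectly, and every orthogonal evaluation — annotation enrichment,
CNS specificity, cross-species conservation — strengthens as the
classification threshold is raised, which is the behavior the method is
designed to exhibit.

Each stage is also exposed individually (`simulate`, `preprocess`,
`trainset`, `fit`, `sweep`, `enrich`, `gtsde`, `homology`); see
`synapred --help`.

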