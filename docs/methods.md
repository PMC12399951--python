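# Methods

This note records the modelling assumptions, numerical choices, and defaults
behind `oncotoc`, and what the synthetic-cohort experiments do and do not
demonstrate.

## Label hierarchy

The prediction space is a rooted tree of cancer categories. The shipped
default has 26 depth-1 major categories and 64 subcategories (90 reportable
labels; 20 branches, i.e. internal nodes with ≥ 2 children). The *topology
statistics* are meaningful; the category membership is illustrative — every
algorithm is topology-generic and the test suite builds its own small
hierarchies. Arbitrary depth is supported (the default is depth ≤ 2; tests
exercise depth 3). The root encodes "some tissue" and carries no
information: it is excluded from label paths and from the metrics.

Internal nodes with exactly one child get no classifier; the child inherits
the parent's score. This is the limit of a softmax over one label (constant
1.0) and preserves the nesting identity without special cases.

## Feature encoding

**Variant block.** Gene-level binary indicators over a fixed panel
(production scale: 227 genes). A gene is set iff it carries at least one
*reportable* variant: classification pathogenic or likely pathogenic, variant
allele frequency ≥ 0.05 and ≥ 5 supporting read alignments, both thresholds
inclusive. Allele frequencies are deliberately not features — only presence.
VUS/benign calls never contribute.

**Expression block.** TPM values are log-transformed (log₂(TPM+1)) —
whether the production pipeline log-transforms is not documented, so this is
an explicit assumption of this implementation. Genes are selected by
training-data variance (production scale ~10k; tests use 20–200; ties break
lexicographically for determinism). Platform harmonization is a
per-platform, per-gene median shift onto the pooled gene median: it removes
a multiplicative platform factor exactly at the median, which a single
scalar shift per platform cannot do under the +1 offset. Shifted values are
then z-standardized per gene with training-set mean/SD; the SD of a constant
gene is floored at 1e-8 so it encodes as exactly 0. Genes missing from a
profile impute to 0 (the training mean); an unseen platform gets an identity
shift plus a warning.

**Sex** is a single entry: male 1, female 0, unknown 0.5 (midpoint, to bias
neither class).

**Tumor content** below the configurable minimum (default 20%) sets a QC
flag and logs a warning rather than rejecting the sample: exclusion is an
upstream laboratory decision, and a library should not silently drop data.

## Branch networks

One multi-class network per branch. Architecture: `n_layers` (default 4)
fully connected layers, hidden width 256, batch normalization and dropout
(rate 0.25) on the hidden layers, ReLU activations, softmax output of width
= number of children. Loss is multi-class cross-entropy at learning rate
0.005. These five values are the documented production recipe; the
remaining training machinery is this package's choice: Adam, batch size 256
(tests use 64), up to 100 epochs with early stopping (patience 10) on a 10%
seeded validation split, He initialization, optional inverse-frequency class
weighting (off by default). The implementation is plain numpy driven by a
single `numpy.random.Generator`, so a fixed seed reproduces parameters
bit-for-bit; per-branch seeds derive from the ensemble seed and the branch's
position in the canonical (root-first, lexicographic) branch order.

Batches of size 1 are skipped (batch normalization is undefined there);
datasets with < 10 samples train without a validation split.

**Routing.** A branch trains on every sample whose truth lies strictly
below the branch parent, labelled by the child subtree containing it.
Samples whose truth *is* the parent (e.g. "carcinoma consistent with known
breast primary", no subtype supplied) carry no child information: they are
excluded from that branch but still train all ancestor branches. Branches
with no data or only one represented child are recorded as untrained and
scored uniformly at inference, with a warning.

## Score propagation and calling

Branch outputs are local probability vectors. Walking from the root (score
1.0) and multiplying each child's branch probability by the parent score
yields per-node scores with three guaranteed identities (enforced to 1e-6 in
tests): majors sum to 1, terminals sum to 1, and children sum to their
parent. Scores are therefore non-increasing with depth. Incoming branch
vectors are validated to sum to 1 within 1e-4.

A call is a greedy descent choosing the max-score child at each level (ties
lexicographic); the reported path is the prefix with score ≥ threshold
(inclusive, default 0.55). The reported granularity thus adapts to
confidence; a subcategory can never be called over a sub-threshold parent
(impossible by monotonicity). Thresholds ≤ 0.5 are rejected outright since
they would permit two sibling calls. Top-1/top-2 majors are reported even
for no-calls.

## Hierarchical metrics

Per sample, with P and T the predicted and truth paths (root excluded):
`hSens = |T ∩ P| / |T|` and `hPPV = |P ∩ C(T)| / |P|`, where the closure
C(T) adds the descendants of the truth terminal to T. The closure implements
granularity credit: a prediction deeper than the truth but inside its
subtree scores 1.0 on both metrics. The four canonical configurations
(exact match; two-level prefix of a three-level truth; wrong terminal;
deeper-than-truth) give (1, 1), (1, ⅔), (⅔, ⅔), (1, 1) and are fixed as
exact test oracles, alongside a brute-force set-arithmetic oracle on random
hierarchies. An equivalent formulation excludes truth-terminal descendants
from the denominator instead; on paths (where predicted nodes are never
double-counted) the two coincide.

Means are taken over *called, truth-mapped* samples only; no-calls and CUP
cases contribute to call rates (reported per stratum) but not to accuracy —
the standard reporting convention for thresholded classifiers.

## Threshold calibration

`sweep` re-calls the cohort at each grid threshold (default 0.51–0.99, step
0.02 — respecting the > 0.5 exclusivity requirement) and records call rate
and mean hPPV, optionally within a stratum (e.g. metastatic cases, as the
operating point is conventionally tuned there). "Balance call rate against
precision" is made reproducible as: maximize the harmonic mean of the two
(ties → lower threshold, maximizing calls); a minimum-hPPV rule and a knee
rule are selectable alternatives. The clinical operating point of 0.55 was
chosen on proprietary data and is the shipped default threshold, not
something this package re-derives.

## Triage rules

Rules 1–7 (module docstring of `oncotoc.triage`) encode the review
procedure: concordant or uncalled cases take no action; a discrepancy
candidate (called CUP, or non-CUP call contradicting the submitted major)
opens a critical-value discrepancy at call score ≥ 0.90; CUP cases with
supporting orthogonal evidence become diagnosis-change eligible, without it
discretionary lineage change; non-CUP discrepancies trigger confirmatory
testing when the submitted label's propagated score is exactly 0 or the
call is high-confidence; everything else is report-only with a discretionary
change offered. The 0.90 threshold is "approximately 90%, at the
pathologist's discretion" in practice; here it is a deterministic,
configurable default. Concordance is judged at the major-category level.
Orthogonal evidence is consumed as curated tri-state flags — it is review
input, never a model feature.

## Synthetic cohorts

The generator emulates the statistical structure the classifier assumes,
not biology: per-node sparse Gaussian effect vectors (default 30% of genes,
effect SD 2 on the log₂ scale) summed along the truth path over a shared
baseline (log₂ mean 5, SD 1), within-class noise SD 1 (multiplied by 1.5
for metastatic samples, modelling their noisier profiles), per-platform
multiplicative TPM factors (defaults 1.0 and 2.5), per-label enrichment of
3 panel genes at variant rate 0.4 over a 2% background with 90% of drawn
variants clearing the reportability thresholds, per-label sex priors
(default 0.5), 5% of samples below the 20% tumor-content QC bar, and CUP
cases as ordinary tumors whose label is withheld but recorded for oracle
evaluation. All draws flow from one seed; node effects are seeded per node
so they are independent of cohort size.

Default effect sizes are intentionally well-separated: held-out performance
near 1.0 confirms the pipeline recovers planted structure, and the
chance-level control (all label-linked channels switched off: zero
expression effects, uniform variant rates) confirms it invents none — its
top-1 accuracy is tested against a pooled binomial 95% CI over three seeded
replicates with 2,000 held-out samples each, a deliberately tighter band
than a single small draw would give. What passing does **not** show:
robustness to real-data phenomena the generator omits — correlated gene
modules, label imbalance, mixed histologies, panel drift across assay
versions, or noise that is structured rather than Gaussian.

Experiment sizes in the test suite (3 majors / 6 subcategories, 600
training and 200–2,000 held-out samples, 200 genes, 30-gene panel) are the
package's standard small-cohort benchmark; production-scale layouts (90
labels, ~10k genes) run identically but are not exercised in the default
suite.

## Known limitations

* Platform harmonization assumes a (near-)multiplicative batch effect;
  gene-specific nonlinear platform distortions are out of scope.
* Probabilities are softmax scores, not calibrated posteriors; the
  calibration module selects an operating threshold but does not recalibrate
  scores.
* The variant channel is presence-only at gene level; CNVs, fusions and
  hotspot identity are not encoded.
* The triage engine fixes thresholds that are discretionary in clinical
  practice; institution-specific review nuances beyond the documented rules
  are not modelled.
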