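# Methods

## The problem

When estrogen-receptor-positive (ER+) breast cancer cells are grown in
direct contact with bone-marrow mesenchymal stromal cells (MSCs), the tumor
cells' transcriptome and proteome acquire molecules they do not express in
monoculture. Some of these are plausibly *borrowed* — physically transferred
from the stromal donor through contact-dependent routes such as tunneling
nanotubes and gap junctions — while others are the tumor cell's own
*intrinsic* response to contact, and a small remainder is induced by soluble
factors alone (conditioned media). `cocultnet` implements the inference
chain that separates these components from bulk expression and proteomic
data, embeds them as layers of a protein-protein interaction (PPI) network,
sharpens the borrowed list by cross-dataset ROC-AUC, and asks whether the
resulting composite signature stratifies patient survival.

## Triage model

Four experimental arms are compared pairwise on log2-CPM expression:
donor monoculture, recipient monoculture, recipient in contact culture
(CC), and recipient in conditioned media (CM).

1. **Donor-high catalog.** Genes up in the donor relative to the recipient
   monoculture (|log2FC| >= 2, BH-adjusted p < 0.05) form the denominator
   of molecules the recipient could possibly borrow.
2. **Contact induction.** Genes up in CC vs recipient monoculture, with
   RNA and protein evidence unioned (per-gene provenance retained).
3. **Partition.** borrowed = induced ∩ catalog; intrinsic = induced \
   catalog; cm_unique = CM-induced \ contact-induced. A gene induced in
   both CC and CM stays in its contact-derived bin with a `cm_shared`
   flag rather than being excluded — soluble induction does not rule out
   contact-dependent transfer, and downstream consumers can filter on the
   flag. When recovery is scored against planted truth, flagged genes
   count as CM calls, because the flag is the pipeline's own CM verdict.
4. **Cross-platform signature.** Genes induced at both the RNA and the
   protein level; these seed the network stage and are the default
   composite signature.

## Differential expression

Counts are normalized to log2(CPM + 1). Library sizes are, by default in
the pipeline, *effective* sizes — median-of-ratios size factors scaled by
the mean raw depth — because with hundreds of strongly induced genes in a
2000-gene panel, raw column sums are inflated in the contact arm and the
naive CPM compresses every fold change by the composition shift
(~0.15-0.6 log2 units here). Plain column-sum CPM remains the
`normalize_log2cpm` default for API compatibility with its documented
formula.

Two per-gene engines are provided. `welch` is the plain unequal-variance
t-test. `moderated` (the pipeline default) shrinks each gene's pooled
variance toward a prior fitted across all genes under a scaled-F model
(moments of log s², trigamma inversion) and tests with augmented degrees
of freedom. With 3 replicates per arm the per-gene variance estimate has
4 df and is so unstable that the plain test cannot rank several hundred
true inductions above 2000-gene BH correction; sharing variance
information across genes is the standard remedy in expression analysis
and restores calibrated power. Thresholds follow the convention
|log2FC| >= 2 and adjusted p < 0.05; both, the engine, and the
normalization are config keys.

## Network stage

The PPI network grows from the cross-platform signature as seeds: every
node within `hops` interaction steps through edges at or above the
confidence cutoff (default 0.4, the STRING "medium" convention) is
retained, plus all qualifying edges among retained nodes. The pipeline
default is `hops=2`: in the synthetic scale-free background (mean degree
~4, far sparser than STRING at medium confidence) one hop of a ~40-150
gene seed set yields a universe nearly equal to the borrowed layer's own
neighborhood, which makes the connectivity test structurally degenerate
(observed overlap can never exceed its expectation). Two hops restore a
universe comfortably larger than the layer neighborhoods — the regime the
analysis is meant for. With a dense real edge table, one hop behaves the
same way and remains the `build_seed_network` default.

Borrowed and intrinsic bins are projected onto the network as layers. A
layer's footprint is the **closed neighborhood** of its tagged nodes
(members plus direct interactors); inter-layer connectivity is the
upper-tail hypergeometric probability of the two footprints' overlap
within the all-nodes universe, computed exactly in log space. The test's
universe, layer sizes and overlap are always reported alongside p; no
printed reference value is ever hard-coded.

## Signature scoring and refinement

The composite score of a signature in a sample is the unweighted mean of
the per-gene z-scores (ddof 1; zero-variance genes contribute 0);
optional per-gene weights are accepted. Group separation is tested by
one-way ANOVA with Tukey HSD correction. Sample clustering is
average-linkage on signature z-scores, by default over Euclidean
distance. Correlation distance (1 − Pearson) is also offered but is a
deliberate non-default: after per-gene standardization of data with a
clean group-mean structure, every sample's z-profile over a single gene
class collapses onto a one-parameter family in which the two elevated
groups (donor and contact) are *always* anti-correlated across genes, so
a pattern-only distance cannot reproduce the observed co-clustering of
contact samples with donor monocultures; the level-sensitive Euclidean
distance does, and it is the default of standard heatmap tools.

Per-gene ROC-AUC uses the rank-sum identity with ties counted 0.5.
Refinement keeps a candidate only if its contact-vs-mono AUC exceeds the
threshold (default 0.85) in **every** validation dataset. Perturbation
recapitulation reports, per triage bin, the fraction of genes whose AUC
separating perturbed from control samples reaches a threshold (default
exactly 1.0 — perfect classification). Over-representation analysis is a
generic hypergeometric over user-supplied GMT collections with BH across
sets; it shares the same hypergeometric core as the network test.

## Survival stratification

Patients are scored with the same composite, then split high/low by a
one-step least-squares fit to the sorted scores: the split minimizing
total within-segment squared error, threshold at the midpoint of the two
segment means, ties toward the smaller split index. A median split
(median patient in the low group at odd n) is available for sensitivity.
Strata are compared by the Kaplan-Meier product-limit estimator and the
two-group log-rank test (1 df, hypergeometric variance). No proportional-
hazards model is fitted: the target analyses report KM + log-rank only.

## Synthetic data generator

The generator is the package's test bed; its defaults define the study
conditions everything is validated under.

* **Design:** four arms x 3 replicates, 2000 genes; planted sets of 150
  transfer, 80 intrinsic and 10 CM genes (seed 7).
* **Counts:** negative binomial with gene-wise dispersion 0.1 (var =
  mu + 0.1 mu²), a standard bulk RNA-seq noise level.
* **Baselines:** background genes lognormal around 150 counts; planted
  genes around 40 — borrowed molecules are characteristically
  low-abundance, and the lower baseline also keeps the contact arm's
  composition shift small.
* **Effects:** the planted log2 fold changes (2.5 each) are guaranteed
  minimum inductions; each gene adds an exponential excess (scale 0.4
  log2 units). The one-sided scatter keeps every planted effect above
  the calling threshold — a symmetric scatter would plant genes whose
  true effect sits below |log2FC| = 2 and is undetectable by design —
  while providing the across-gene heterogeneity real data shows. The
  donor expresses transfer genes an extra 2 ± 1 log2 units above its
  contact-arm elevation, and background genes differ between the two
  cell lines by lognormal factors (log2 sd 1), so the donor-high catalog
  contains realistic cell-line-difference genes beyond the planted set.
  A `cc_admixture` parameter can blend residual donor signal into the
  contact arm (imperfect tumor-cell enrichment from the 1:9 co-culture);
  it defaults to 0 because it also dilutes the recipient's intrinsic
  induction.
* **Proteome:** per-gene detection is Bernoulli with probability logistic
  in mean log2-CPM abundance (midpoint 7, slope 1), reproducing the
  low-abundance dropout of isobaric-tag quantification. Detected genes
  inherit the generator's per-gene RNA fold change plus independent
  N(0, 0.3) platform noise; the p-value is a z-test against that noise.
* **Network:** Barabási-Albert background (m = 2) over planted genes plus
  extras, with 300 excess transfer-intrinsic edges planted; the control
  applies degree-preserving double-edge swaps, so planted and control
  differ in inter-layer wiring but not in degree sequence.
* **Cohort:** a latent high state (Bernoulli 1/2) shifts signature genes
  by 1.5 sd and multiplies an exponential baseline hazard (median 60
  months) by the hazard ratio (default 2); censoring is independent
  exponential at the baseline rate, giving ~40% censored records.
* Gene-intrinsic quantities (baselines, per-gene effects) are drawn from
  the truth seed so replicate datasets of one truth share them; only the
  sampling noise varies with the per-call seed. Planted truth is written
  to a JSON sidecar next to every fixture and no pipeline stage reads it.

What the generator does *not* emulate: batch effects, gene-gene
correlation beyond the planted group structure, isoform/probe ambiguity,
non-exponential hazards, and real PPI topology beyond scale-freeness.
Passing recovery tests therefore demonstrates the pipeline's logic and
calibration, not performance on any particular real dataset.

## Numerical and degenerate-case choices

* Hypergeometric tails via exact log-space summation; verified against
  combinatorial enumeration to 1e-12 relative for all universes <= 60.
* Zero-variance two-group separations report p = smallest positive float
  with a `degenerate` flag; identical constant groups report p = 1.
* BH adjustment preserves input order; p outside [0, 1] is an error.
* The step fit breaks SSE ties toward the smaller split index; constant
  vectors are degenerate with threshold equal to the constant.
* Duplicate expression rows collapse by sum (counts) or max (log scale);
  symmetric duplicate edges keep the maximum confidence; self-loops drop
  with a warning.
* STRING scores are auto-detected: any score > 1 triggers division by
  1000.

## Problem sizes

The default study (2000 genes, 12 samples) runs the full pipeline in
about two seconds; the test suite's largest computations are 200
simulated cohorts for log-rank calibration and 40 simulated networks for
the wiring contrast, chosen so the complete suite finishes in well under
a minute while leaving the Monte-Carlo acceptance margins comfortable.

## Known limitations

* The triage cannot decide whether a borrowed molecule moved as RNA or as
  protein; provenance records which platforms saw it, nothing more.
* With every planted CM gene also induced in contact culture (as the
  emulated design prescribes), `cm_unique` is empty or near-empty by
  construction; CM genes surface through the `cm_shared` flag.
* Real-cohort preprocessing (probe collapsing, cohort merging) is out of
  scope; cohort expression units are caller-declared.
* The moderated engine assumes roughly exchangeable gene variances on the
  log scale; grossly heteroskedastic data would call for an
  abundance-dependent variance trend, which is not implemented.
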