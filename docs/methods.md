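# Methods

## Quantification model

The unit of quantification is the peptide-spectrum match (PSM) count per
protein and sample. NSAF (normalized spectral abundance factor) corrects
the count for protein length — longer proteins yield more observable
peptides — and normalizes within each sample:

    NSAF_k = (PSM_k / L_k) / Σ_i (PSM_i / L_i)

NSAF is compositional: a sample's values sum to exactly 1, so only
*relative* abundance is meaningful and any per-sample change in total
spectral yield cancels. Zeros are kept as exact zeros; no pseudocount is
introduced at quantification. Values are stored on a configurable
reporting scale (default ×1000), chosen so that typical values for a
~1,000-protein dataset land near 1 rather than 1e-3; the raw compositional
values are always recoverable and all sum-to-one contracts are stated on
them. The exact reporting scale behind published NSAF tables of this kind
is rarely stated; ×1000 reproduces their magnitude and is an explicit
assumption here, configurable per call.

"Detected" means PSM count > 0 throughout; the presence filter and the
detection sets therefore run on counts, not NSAF (their zeros coincide).

## The three-condition differential rule

For a reference treatment A and treatment of interest B, a protein is DE
iff:

1. it is detected in every replicate of A or of B;
2. a two-sided two-sample t-test on the per-replicate NSAF values gives
   p ≤ α (default 0.05), **or** the protein has zero detections in every
   replicate of one treatment;
3. |signed fold| ≥ 1.5, where the fold is the ratio of treatment-mean
   NSAF values (zeros included in the means), reported as +mean_B/mean_A
   when abundance rises and −mean_A/mean_B when it falls. A fold with one
   zero mean is the "absent" sentinel (±Inf) and satisfies this condition
   by definition.

Choices where the procedure is underdetermined:

* **t-test variant.** Student's equal-variance test is the default — the
  classical choice at n = 3 per group; Welch is available by config.
* **Fold on means, not replicate-wise.** The fold uses arithmetic
  treatment means of NSAF; published fold values of this style are
  consistent with mean ratios.
* **No multiple-testing correction in the call.** The rule uses raw
  p-values by design; a Benjamini–Hochberg q-value column is emitted for
  transparency but never consulted by the call.
* **Degenerate variance.** Zero variance in both groups with unequal
  means → p = 0 (a deterministic difference, the limit of the t
  statistic); with equal means → p = 1.
* **DE universe.** The retained set from the presence filter over the
  *full* design, computed once and shared by every pairwise comparison.

The one-way ANOVA scan across all treatments is a classical fixed-effects
F-test computed from explicit sums of squares (so the degenerate
zero-within-variance cases can be handled deterministically), with the
F-distribution tail from scipy.

### Calibration and power of the rule

Two properties of the rule are worth knowing and are verified by
simulation in the test suite:

* **Calibration.** Under a global null with every protein comfortably
  above the detection limit, the rule's call rate is below α: the calls
  are an intersection of t-test rejections with the fold filter, which is
  monotone. At *shallow* sampling depth, however, multinomial sampling
  zeros occasionally produce all-replicate absences for low-abundance
  proteins even with no detection-failure mechanism; these fire the
  absence branch, which is deliberately test-free, and add on the order
  of 0.5–1 percentage point of null calls. This is a detection-limit
  phenomenon intrinsic to presence/absence-aware rules, not a property of
  the t-test; the calibration experiment therefore runs at depth
  (500k PSM/sample for 2,000 proteins) where the detection limit is
  disengaged, and this paragraph is the record of the shallow-depth
  behavior.
* **Power.** For 4-fold planted effects at n = 3, recovery depends
  sharply on counting depth. The recovery experiment runs at "moderate
  counts" — defined here as counting noise comparable to, not dominating,
  the biological replicate CV (median expected count ≈ 24 PSM per
  protein; counting CV ≈ 0.2 against replicate CV 0.25) — where recall
  exceeds 0.8. At the pollen fixture's own depth (20k PSM/sample, median
  expected count ≈ 5) the low-abundance half of the proteome is
  counting-noise-dominated and expected recall drops to ~0.6–0.75; the
  fixture-level test asserts that measured level. Passing tests therefore
  demonstrate the rule's behavior in each stated regime, not a universal
  recall guarantee.

## Multivariate analyses

PCA treats samples as observations and retained proteins as variables,
mean-centered and unscaled by default (unit-variance scaling and a
log2(1+x) transform are exposed as flags but are not the default; the
centering-only convention is the common one for NSAF matrices). Component
signs are fixed so each loading vector's largest-magnitude entry is
positive. The loading-sum profile takes the n most extreme loadings of a
component (ties broken by accession order for determinism) and sums the
selected proteins' treatment-mean NSAF per treatment — a compact view of
which conditions a component separates.

Treatment profiles for clustering are each protein's per-treatment mean
NSAF rescaled to sum to 1, so clustering groups response *shapes*.
k-means is Euclidean with k-means++ seeding, best inertia over
``n_restarts`` (default 50) restarts, deterministic given (seed,
restarts); rows are canonicalized by accession sort before seeding so the
result is input-order invariant. k defaults to 30 — the historical choice
for this workflow, treated as configuration, not something the package
selects. The clustering and PCA machinery is scikit-learn's, behind this
module's deterministic conventions.

## Enrichment

Over-representation of a GO term in a foreground list against a
background is the upper-tail hypergeometric probability of observing at
least the seen number of annotated proteins, with Benjamini–Hochberg
adjustment across all tested terms and enrichment declared at q ≤ 0.05.
Only directly annotated terms are tested; there is no GO-graph ancestor
propagation. The background defaults to the full annotation map supplied
by the user; restricting to the detected dataset is an option. This is a
standard over-representation computation, stated as such — not a
reproduction of any particular web service's internals.

Venn partitions are computed exactly: every element of the union is
assigned to its membership region, so region sizes always partition the
union; percentages round half-away-from-zero to integers (as do the
up/down percentages in the DE summaries).

## Synthetic data generator

The generator draws, per sample, a multinomial with a fixed spectral
budget (``total_psm_per_sample``, default 20,000) — total PSM yield per
run is an instrument property, which also makes the simulated data
compositional like NSAF itself. Sampling weights are
abundance × length × log-normal replicate jitter:

* **lengths** log-uniform on 100–1,200 aa, so the NSAF length correction
  is exercised non-trivially (a pure-abundance weight would make it
  vacuous);
* **baseline abundance** log-normal with σ = 1.2 (a long-tailed proteome
  spanning ~2 orders of magnitude);
* **replicate jitter** log-normal with σ = 0.25, in the 20–30% CV range
  typical of label-free biological replicates;
* **treatment effects** multiply designated proteins' abundance in
  designated treatments (default effect 4-fold, matching the scale of
  changes such experiments highlight);
* **detection dropout** is Bernoulli per protein and sample with a
  logistic probability in log expected count (midpoint 1 PSM). The slope
  (3.0) makes the logistic track 1 − exp(−E[count]) — the missingness
  that pure counting statistics would impose — for expected counts above
  the midpoint, so detection failure supplements rather than dwarfs
  Poisson-level noise at moderate abundance while still producing the
  all-replicate absences the DE rule's absence branch exists for.

`pollen_fixture` is the canonical structured dataset: 1,000 proteins,
4 treatments × 3 replicates, ~72% of proteins carrying MapMan-style bins.
Heat stress (P-HS) down-shifts the translation-machinery bin 4-fold and
the TCA bin 3.3-fold and up-shifts a small heat-stress bin 4-fold;
ethephon pre-treatment before heat stress (P-E-HS) attenuates every shift
toward control. Bin-linked toy GO terms (e.g. GO:0006412 on ~90% of the
translation bin) make the planted structure recoverable by enrichment.

What the generator does *not* emulate: peptide-level structure and shared
peptides, protein inference ambiguity, retention-time or intensity
information, batch effects, and missingness mechanisms beyond the
abundance-dependent logistic. Tests passing on synthetic data show the
pipeline recovers structure its statistical model can express; they do
not certify behavior under real-data artifacts outside that model.

## Numerical conventions

* NSAF columns sum to 1 within 1e-9 (exactly up to float summation); an
  all-zero sample yields an all-zero column with a warning.
* DE tables sort by |fold| descending, sentinels first, ties by
  accession; all writers emit strict TSV (tab, no quoting, "." decimal,
  NA for undefined, Inf/−Inf for the absence sentinel) and sort rows by
  accession unless the producer supplied a rank column, so equal inputs
  give byte-identical files.
* All randomness flows from explicit seeds; the pipeline logs its seed
  and every stage's parameters.

## Problem sizes in the shipped tests

The shipped suite runs the calibration null at 2,000 proteins × 200
draws (two treatments, 3 replicates), the recovery simulation at 1,000
proteins, and the end-to-end fixture at 1,000 proteins × 12 samples —
sizes chosen to exercise the asymptotics the properties are about while
keeping the whole suite under a minute on one CPU.
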