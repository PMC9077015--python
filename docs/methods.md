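# Methods

## Scope and data flow

The package reimplements a two-arm analysis. Arm 1 (systems pharmacology)
is purely set algebra over tabular inputs: an ADME screen, a rank/Z filter
on predicted targets, and pathway annotation. Arm 2 (metabonomics) turns
labeled serum spectra into a normalized bucket matrix, fits latent-variable
models, calls biomarkers, and scores pathway enrichment. The integration
stage intersects the two pathway sets and maps the overlap back through
protein → compound → herb relations. No stage queries a live database:
pathway membership and topology come from files (a GMT-like membership
format plus an edge list), and ADME/Z-scores are inputs, not predictions.

## ADME screening

Thresholds: OB ≥ 30 % and DL ≥ 0.18 and HL ≥ 4 h (inclusive), BBB > 0.3
(strict). Comparisons are exact floating-point comparisons with no
epsilon: a compound at BBB = 0.3 is rejected, one at OB = 30.0 retained.
Records with a missing descriptor are rejected with a logged reason rather
than raising, since real database exports are patchy. A whitelist of
(compound, herb) pairs bypasses the screen entirely; the default carries
two osmolytes of Radix Angelicae Sinensis (taurine, betaine) and six
volatile-oil constituents of Cinnamomi cortex, each a documented active
with sub-threshold DL or BBB. Compounds occurring in several herbs are
merged to a single record with a herb set, so the herb–compound network
has one node per compound with degree equal to its herb count; both the
union count and the per-herb sum are recoverable from the outputs.

## Spectral preprocessing

* **Calibration.** The lactate CH₃ doublet is located as the two highest
  local maxima within ±0.1 ppm of δ 1.33; the axis is shifted so their
  midpoint lands exactly on target. Detection failure raises an error
  naming the sample.
* **Bucketing.** Buckets are 0.004 ppm wide, left-closed/right-open,
  anchored at the low edge of the region δ 0.5–8.5 (the anchor side is
  configurable since either convention is defensible). A bucket whose
  interval intersects an exclusion window — by default the residual-water
  region δ 4.7–5.2 — is dropped whole; partial buckets would bias areas at
  the exclusion boundary. The defaults give 1875 retained buckets. Bucket
  values are trapezoidal integrals of the piecewise-linear interpolant on
  the native grid refined with the bucket edges, summed per bucket locally
  so that intensity outside a bucket has exactly zero influence on it.
* **Normalization.** Total-sum: each row divided by its own total, which
  removes per-sample dilution; totals are kept for audit. Row sums are 1
  to 1e-12 by construction.

## PCA and OPLS-DA

Columns are mean-centered and unit-variance scaled by default (the common
SIMCA-style setting); Pareto scaling is available because it is the NMR
community's other norm, and the choice is recorded on the results object
via the stored scale vector. PCA is a plain SVD of the scaled matrix with
per-component R²X.

OPLS-DA codes the two classes y ∈ {0, 1}, centered. The predictive weight
is the normalized X–y covariance direction w ∝ Xᵀy. For each of the
`n_orth` orthogonal components (default 1, the standard choice for a
two-class model), the X-loading part orthogonal to w is extracted,
normalized, and its component deflated from X; the predictive score
t = Xw, loading p, and y-loading q are computed on the deflated matrix.
By construction every orthogonal score vector is exactly orthogonal to t.
R²X splits into predictive and orthogonal parts; R²Y = 1 − ‖y − qt‖²/‖y‖².
Sign indeterminacy is fixed by making the largest-|element| entry of each
loading positive, so repeated runs agree exactly.

Q² uses K-fold cross-validation (default 7 folds, SIMCA's default count):
folds are assigned round-robin over a seeded shuffle; each training split
must retain both classes or the run errors out. Held-out samples are
scaled with training parameters, deflated with the training orthogonal
components, and predicted as ŷ = qt + ȳ_train; Q² = 1 − PRESS/SS with SS
the total centered sum of squares of y. Q² ≤ R²Y on every fit we test,
but the bound is empirical, not algebraic.

## Biomarker selection

Correlation loadings are Pearson correlations r between the predictive
scores and each bucket, oriented by sign(q) so that positive covariance
always means "higher in the case group" regardless of the loading sign
convention; the plotted height is the covariance in original units. The
threshold is the exact critical value of the null Pearson correlation,
r\* = t\*/√(t\*² + n − 2) at the two-tailed α quantile of Student's t.
`n` defaults to the **per-group** sample size of the design (8 here,
giving the published 0.707 at α = 0.05) rather than the pooled 16 — this
matches the reporting convention for these coefficient plots and is the
more conservative choice.

Bucket calls are lifted to metabolite calls by majority vote over the
metabolite's annotated buckets (annotation = ppm windows per metabolite);
the direction is the sign of the mean covariance over its passing buckets.
Passing buckets outside every window are reported as `unassigned` rows,
never silently dropped. The lifting rule is this package's choice; the
source workflow selects metabolites but states no rule.

## Univariate statistics

Per metabolite: one-way ANOVA over the three groups, then the two pairwise
contrasts of interest tested with pooled-variance t statistics on the
ANOVA within-group mean square (the SPSS-style "ANOVA with Bonferroni"
construction); Welch's t-test is available as an alternative engine since
the source describes both. The Bonferroni family is all metabolites ×
both contrasts — the most conservative reading — and p_adj = min(1, m·p)
exactly. Stars: * < 0.05, ** < 0.01, *** < 0.001 on adjusted p.

## Pathway enrichment and impact

Matching is by compound identifier (KEGG ids preferred); lipid-class and
glycoprotein panel entries are excluded upstream because they have no
single small-molecule identity, and the TMAO/betaine composite resonance
is split into both constituents — the bundled 20-entry serum panel thus
yields an 18-metabolite query. The over-representation p-value is the
upper-tail hypergeometric probability of the observed hit count, with the
universe defaulting to the distinct compounds of the loaded library
(mirroring tools that use their reference library as background; the
universe is configurable because published p-values depend on it).
−log(p) is the natural log. Impact is the sum over hit compounds of
betweenness centralities — computed on the pathway's undirected simple
compound graph — normalized so the pathway's importances sum to 1; graphs
with no positive centrality (≤ 2 nodes, complete graphs) get impact 0.
Rows are sorted by raw p with name tie-breaks for determinism; cutoffs
are p < 0.05 (significant) and impact > 0.1 (high impact). No
multiplicity adjustment is applied at this stage, matching the source
workflow's raw-p selection.

## Integration

Pathway names from the two arms are free text from different sources, so
matching is by canonicalized name: case-fold, unify "/" with " or ",
strip punctuation, collapse whitespace. Stereochemistry prefixes survive
as tokens because hyphen removal is applied uniformly to both sides.
Reverse mapping keeps exactly the proteins annotated to an overlapping
pathway, the compounds hitting a kept protein, and the herbs containing a
kept compound; node degrees are those of the induced subgraph, matching
how such networks are drawn. Exports are SIF and GraphML (round-trip
tested), both Cytoscape-consumable.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design: three groups (control, disease
model, treated) of 8 animals, spectra on δ 0.2–9.0 at 0.0005-ppm
resolution. Metabolite signals are fixed Lorentzian line templates
(HWHM 1.5 Hz ≈ 0.003 ppm at 500 MHz, J fixed at 7 Hz) positioned at the
serum panel's chemical shifts; the glutamate envelope is lopsided so it
does not sit directly on the methionine singlet, which would be
unresolvable at this linewidth. Base concentrations are serum-realistic
relative magnitudes (glucose, lactate, lipids large; aromatic amino acids
small). Group effects apply the panel's reported directions as fold
changes (default 2.0 — the source reports directions and significance
only, so the effect size is a free parameter chosen to represent a clear
but not extreme metabolic shift). Noise: per-metabolite log-normal
factors with CV `noise_cv` (default 0.1), a per-spectrum log-normal
dilution factor with the same CV (removed by normalization), a small
random axis misalignment (undone by calibration), an additive noise
floor, a smooth deterministic baseline, and a large water hump confined
to δ 4.7–5.2 so the exclusion rule is consequential. With `noise_cv = 0`
generation is fully deterministic. All randomness derives from the single
config seed through per-generator substreams.

Not emulated: time-domain acquisition (FID, phasing, apodization), real
J-coupling physics, peak-position drift with pH/ionic strength, and
macromolecule baselines. Passing recovery tests therefore demonstrate the
statistical pipeline's correctness under a faithful spectral overlap
structure, not robustness to raw-data artifacts.

## Numerical choices and known limitations

* Simulation sizes: recovery statistics use 20 generator seeds at the
  default design (3 × 8 animals); the permutation null of Q² uses a
  40-sample structureless design with 100 permutations, where the
  statistic's null behavior is stable.
* Total-sum normalization induces closure: when many metabolites fall in
  one group, unchanged metabolites' normalized shares rise. With the
  default effect table the planted ups and downs roughly balance the total
  integral, keeping this artifact below the |r| threshold, but an
  occasional unchanged singlet (e.g. acetate) can cross 0.707 at an
  unlucky seed — a real and well-known artifact of this normalization,
  not a code defect.
* The critical-|r| threshold assumes bivariate normality of bucket values
  and scores; bucket intensities are only approximately normal.
* Published model statistics (R²X/R²Y/Q² of the original score plots) and
  absolute enrichment p-values depend on unreleased spectra and an
  unrecorded background universe, and are not reproduction targets; the
  bundled pathway-analysis table is used as a reference input instead.
* One reference −log(p) row (p = 0.042181 printed next to 3.2688) is
  inconsistent with the natural log (≈ 3.1658) and is treated as a typo;
  the recomputed value is used.
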