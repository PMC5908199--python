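# Methods

## The analysis chain

The package analyses a two-group cohort — subjects who develop broadly
neutralizing antibodies (bNAb, defined as plasma neutralizing ≥ 40% of a
44-virus multi-clade panel at 3 years post-infection) versus subjects
who do not — from antibody Fc effector measurements taken early in
infection. The chain is: raw assay readouts → per-assay composite
scores → negative-control thresholding → per-subject composite scores →
univariate FDR screen → multivariate classification with permutation
validation. Sequence divergence/diversity metrics sit alongside as an
independent check that group differences are not explained by viral
distance from the assay antigens.

## Assay scores and thresholding

ADCP and ADCD are products of a geometric MFI and a percent-positive
readout (units %×MFI); ADCC is a background-subtracted percentage
(no-IgG wells); ADCT is a percentage of total effector cells.
Percentages are carried on the 0–100 scale to match how the assays are
reported.

Positivity thresholds come from HIV-negative control donors: mean + 3 ×
sample SD (ddof = 1; the convention when the population SD is unknown)
per antigen × function pair, subtracted from subject scores and floored
at 0. Flooring is a choice: negative residuals after background
subtraction have no physical meaning and downstream products/Z-scores
require non-negative scores. The per-antigen-function application (vs a
global threshold) is the conservative reading and is how
`score_table` applies it; `negative_threshold`/`apply_threshold` are
exposed separately so a global policy can be composed if wanted.

Plate normalization divides by the plate's HIVIG reference score and
multiplies by the grand mean of references, making the reference itself
plate-invariant and leaving single-plate runs untouched.

## Composite scores

**Polyfunctionality.** Each function's scores are standardized across
the analysis cohort (sample SD; HIV-negative controls excluded) and the
four Z-scores summed per subject. "Standard deviation of the mean"
ambiguity is resolved as the SD of the values, not the SEM — SEM would
rescale every Z-score by √n and change no ranking. Totals sum to ~0
across the cohort by construction; the score is invariant to any
positive affine rescaling of a function's raw scale.

**Subclass diversity.** (IgG2 + IgG4)/IgG1 on antigen-specific MFIs —
scale-invariant, so unaffected by detector gain. In the pipeline the
ratio denominators are floored at 1 MFI unit (the instrument's
effective detection floor): a below-detection IgG1 then yields a large
finite ratio rather than an undefined one, and no subject is dropped
(no data are imputed anywhere).

**Classification metrics.** Sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy (TP+TN)/N as percentages, with the bNAb group as
the positive class.

## Inferential statistics

All comparisons are non-parametric. Mann-Whitney U uses the exact
permutation null for combined n ≤ 12 without ties, else the
tie-corrected normal approximation (both via scipy). "Kruskal-Wallis
with Tukey correction" is not a standard pairing; post-hoc pairwise
comparisons are implemented as Dunn's rank-sum z-tests with a
configurable family-wise adjustment (Holm default; Bonferroni, BH, or a
studentized-range "tukey" variant on rank means). Note rank tests
saturate: at n = 10 per group and k = 3, complete separation of
adjacent groups caps the Dunn z at ~2.54, so adjusted p-values below
~0.01 are unattainable for adjacent pairs regardless of effect size.

Feature selection Spearman-correlates each candidate feature with the
group label coded 0/1 (rank-biserial equivalent), adjusts p-values by
Benjamini-Hochberg step-up across all candidates, and keeps features
with adjusted p < FDR (default 5%). The screen uses single-timepoint
data (the 6-month snapshot the generator produces).

## Multivariate classification

Features are Z-score standardized before PCA and the forest. The
classifier is a 500-tree random forest (Gini criterion,
√(n_features) candidates per split, unlimited depth, bootstrap
resampling) validated by the out-of-bag estimate: each subject is
predicted by the majority vote of trees whose bootstrap sample excluded
it. The confusion matrix, sensitivity/specificity/accuracy and the
mean-decrease-in-Gini importance ranking all come from this OOB fit
(scikit-learn).

The permutation test refits the forest on uniformly shuffled labels and
counts shuffles whose OOB accuracy strictly exceeds the observed one
(the strict convention can be relaxed to ≥, and the (k+1)/(N+1)
estimator is exposed, since strict counting yields exactly 0 under
complete separation). Because a 23-subject OOB accuracy lives on a 1/23
lattice, ties with the observed accuracy are common and are counted
separately (`n_tied`); the randomized quantity
(n_greater + U·(n_tied+1))/(N+1) is exactly uniform under label
exchangeability and is what the calibration tests check.

Refitting tens of thousands of forests is infeasible with a
general-purpose forest implementation at this cohort size (millisecond
Python overhead per fit dominates), so the permutation loop uses a
compiled (numba) evaluator implementing the identical algorithm —
bootstrap, CART/Gini, √d feature subsampling, OOB majority vote with
ties toward the negative class — at ~2.6 ms per 500-tree forest. The
observed accuracy inside the permutation test uses the same evaluator,
so the comparison is like-for-like; the evaluator is cross-checked
against scikit-learn's OOB accuracy in the test suite. Permuted-model
accuracy is OOB accuracy (not resubstitution), for consistency with the
observed model.

## Sequence metrics

Distances are uncorrected p-distances: the proportion of differing
sites after excluding columns with a gap or N in either sequence
(pairwise deletion; complete deletion available as an option).
Divergence is the mean p-distance (%) of a subject's sequences from a
named antigen reference; diversity is the mean p-distance over all
C(n,2) unordered pairs within a subject × timepoint set. No
evolutionary-model correction (e.g. Jukes-Cantor) is applied — the
uncorrected distance is the conservative default and matches the
p-distance convention of standard phylogenetics tools; the test suite
pins agreement with `ape::dist.dna(model = "raw", pairwise.deletion =
TRUE)` on a frozen small alignment. Mixed case is upper-cased;
characters outside {A,C,G,T,N,-} are an error rather than silently
treated as ambiguous. Alignment is upstream; reading frames are
ignored (distances are nucleotide-level).

## The synthetic cohort generator

The generator is the package's stand-in for a real cohort: 13 bNAb +
10 no-bNAb subjects and 5 HIV-negative controls at a 6-month timepoint,
with three HIV envelope antigens (gp120 ConC-like, gp140-like, gp120
CAP45-like), four effector functions, seven FcγR/C1q binding reagents
on two antigens, five subclass channels on the primary antigen, and
clinical covariates.

Each feature is group-mean + effect + Gaussian noise on its native
scale, floored at 0 (MFIs, percentages) and capped at 100
(percentages). Effects are standardized shifts (bNAb − no-bNAb, SD
units) per feature family. Defaults: +1.2 for ADCD, ADCT, FcR and C1q
binding and CXCL13; +1.5 for IgG2 and IgG4; +0.8 for total IgG; +1.0
for AID; −1.0 for CD4; +3.0 for breadth (the groups are defined by a
breadth threshold); 0 for ADCP, ADCC, IgG1, IgG3 and viral load (the
groups are matched on viral load). A ~1.2 SD shift is the magnitude
detectable at α = 0.05 with 13 vs 10 subjects, i.e. the size implied by
features reported as significantly different at this cohort size;
baseline means/SDs are plausible instrument-scale values (e.g. MFIs in
the 10²–10⁴ range, CXCL13 tens of pg/ml, CD4 ~450 cells/µl).

Negative-control rows draw the HIV-specific measurement columns from
the baseline scaled by 0.2 (controls show low but nonzero background
binding); clinical columns are left at baseline with viral load and
breadth set to 0 — scaling a healthy donor's CD4 count by 0.2 would be
biologically backwards, and controls only feed the thresholding step.
Optional multiplicative log-normal plate effects scale MFI columns, and
matching per-plate HIVIG reference scores are attached so
`plate_normalize` can undo them.

What the generator does **not** emulate: between-feature correlations
(features are independent given group — real effector functions and
binding MFIs are strongly correlated), longitudinal within-subject
kinetics, heavy-tailed/heteroscedastic assay noise, and batch
structure beyond the simple plate factor. Passing tests therefore
demonstrate that the chain recovers planted, independent group shifts
at this sample size — not that it would behave identically on
correlated real panels.

The sequence generator mutates a fixed reference independently per
site (gap with probability g, else substitution to one of the three
alternative bases with probability r) and records the true substitution
count per sequence, giving a closed-form binomial expectation
(divergence ≈ 100·r%) for calibration tests.

## Problem sizes and numerical choices

Simulation-based checks use: 1000 zero-effect cohorts for FDR
calibration; 200 replicate cohorts × 500 shuffles (100-tree forests)
for the permutation-uniformity check; 10,000 shuffles at the full 500
trees for signal-recovery runs; 300 null cohorts in the acceptance
script. These sizes give Monte-Carlo standard errors comfortably below
the margins being tested while keeping a full run to minutes on one
CPU.

Assertions on planted-signal recovery are calibrated from the binomial:
with ~0.78 per-feature power at the BH threshold, at least 13 of the 25
shifted candidates (3σ lower bound) must be selected. Determinism:
every generator and both forest implementations are seeded; pipeline
stage seeds derive from the master seed via a single generator, so a
rerun is byte-identical. Z-standardization raises on zero-variance
input rather than emitting NaN; PCA and the forest refuse missing
values (no imputation by design).

## Known limitations

- Independent-feature simulation overstates how cleanly feature
  selection separates families relative to correlated real data.
- The permutation evaluator's tie-breaking (toward the negative class)
  matches scikit-learn's argmax convention but differs from R
  randomForest's random tie-breaking; with 500 trees OOB vote ties are
  rare.
- Exact Mann-Whitney enumeration is limited to combined n ≤ 12 without
  ties; beyond that the tie-corrected normal approximation is used.
- Dunn post-hoc p-values saturate at small n (see above) — a
  significance claim finer than the rank lattice permits is not
  obtainable, whatever the correction.
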