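# Methods

This note documents the models, conventions and numerical choices behind
`nmosdmri`, in the order data flows through the pipeline.

## The data model

The unit of input is the adjudicated lesion record, not pixels: each scan
carries binary feature observations, lesion counts and (for spine imaging)
explicit lesion spans.  All analysis is per patient.  A feature is
*first*-present if seen on the earliest scan of the relevant region — first
is resolved per region, because brain and spine imaging happen on different
dates — and *ever*-present if seen on any scan.  Three criteria (normal
brain, Paty, Barkhof) are defined only on first brain imaging and carry
their first value as their ever value.  When a patient has no imaging of a
region, the region's features are *missing*, and the patient drops out of
every denominator that needs them ("the denominator was reduced").
Optic-pathway features are assessed on orbital imaging or, when none
exists, on brain imaging; a switch (`optic_from_brain=False`) restricts
them to dedicated orbital imaging for sensitivity analyses.

Spinal-cord geometry uses 44 hemi-vertebral levels (level 1 = superior half
of C1 … level 44 = inferior half of L3); span length is `end − start + 1`
hemi-levels.  A lesion is *long* (longitudinally extensive) at ≥ 6
hemi-levels (≥ 3 vertebral bodies), otherwise *short*; the classes
partition all lesions.  Contiguity is part of a span's definition —
separately recorded lesions are never merged, so the "pseudo-long"
appearance of coalescing lesions is an upstream reading decision, which can
be tagged on the lesion for display.  Whole (axial) lesions involve all 8
central+peripheral quadrants and therefore also count as central.

Scan timing: a scan is relapse imaging when a documented relapse falls
within 90 days before to 30 days after the scan, both ends inclusive; day
resolution throughout.

## Association statistics

Each feature yields a 2×2 table over non-missing patients.  Odds ratios
use the Haldane–Anscombe correction — +0.5 added to **all four** cells
whenever any cell is zero — and a Woolf log-normal 95% CI computed on the
same (possibly corrected) cells.  The correction is applied to the CI as
well as the point estimate: the standard error `√(1/a+1/b+1/c+1/d)` is
undefined on zero cells, so a CI on uncorrected cells would not exist in
exactly the cases the correction targets.  No multiple-testing adjustment
is applied anywhere, matching the original analysis (matched cohorts,
prior evidence for the candidate features, observational data); results
carry no adjusted-p field at all.  Sensitivity is `a/(a+b)` (NMOSD as the
target condition), specificity `d/(c+d)`.  Mann–Whitney count comparisons
are delegated to scipy.

## Classifiers

* **Paty**: ≥ 3 white-matter lesions > 3 mm, or 2 with one periventricular.
* **Barkhof**: ≥ 3 of {Gd lesion or ≥ 9 T2 lesions; ≥ 1 infratentorial;
  ≥ 1 juxtacortical; ≥ 3 periventricular}.
* **Score**: class scores are weighted sums of present binary features;
  *diagnose NMOSD iff NMOSD-score × ratio > MS-score*, strict inequality,
  default ratio 3.5 — a tie is "not greater", hence MS.  The default
  feature lists are the significantly associated features of each disease
  with double weight on longitudinally extensive cord and bilateral optic
  nerve lesions (NMOSD) and ovoid lesions (MS); the original fitted weights
  are unpublished, so this default is a labelled reconstruction, fully
  overridable by YAML config.  A regional mode (optic/brain/cord sub-scores
  with per-region cut-offs) is retained but off by default, since summative
  scoring gave the better original results.
* **Tree / rulesets**: a binary decision-tree engine and `and/or/not`
  boolean rulesets load from config files and validate feature references
  at load time.  The shipped example tree is illustrative, not a fitted
  model; named external criteria should be transcribed by users from their
  original publications into ruleset configs.

Missing features evaluate as absent inside every classifier; a patient
lacking *all* the imaging a classifier reads is unclassifiable and is
excluded from that classifier's denominator (count reported).  In the
tree, missing and absent both take the N branch.  Paty/Barkhof, as
MS-directed brain criteria, predict NMOSD when **not** met.

## Evaluation: the weighted-mean convention

With NMOSD positive and MS negative, every metric is computed twice (each
class in turn as positive) and combined as

    weighted(m) = (m_NMOSD · n_MS + m_MS · n_NMOSD) / (n_NMOSD + n_MS),

i.e. each class's metric weighted by the **other** class's size.  Among the
conventional schemes (macro, prevalence-weighted, prediction-weighted,
opposite-weighted) this is the only one that reproduces the reference
results table; the test suite re-derives that discrimination by brute
force.  Under it the weighted FP rate satisfies the exact identity
`(FP + FN) / total`.  The column named "ROC area" is the unweighted mean
of the two per-class TP rates — single-operating-point balanced accuracy —
since the classifiers are hard rules with no sweepable threshold; the
traditional column name is kept with this glossary note.  Reports print at
3 decimals, half-up.  Undefined cells (zero predicted positives) propagate
as NaN, never silently as 0.

Two cells of the stored reference table are internally inconsistent with
their own confusion counts: one FP rate printed as 4.352 where the identity
gives 0.352, and one printed as 0.324 where the identity gives 0.327 (its
companion row with identical FP+FN prints 0.327).  The table is stored
verbatim and the two corrections are applied explicitly and visibly in
code.

## The score search

The original models were explored by hand in a spreadsheet; the package
formalises that exploration so it is reproducible: (1) cut-offs on a
single-class score are escalated in unit steps until specificity reaches
1.00 or sensitivity falls below 0.50, the full trajectory being returned
for audit; (2) greedy refinement proposes single-feature removals (in
feature order), then single-step weight increments along the {1,2,3} grid,
accepting the first proposal that strictly improves (specificity,
sensitivity) lexicographically while keeping sensitivity ≥ 0.50; (3) the
combination ratio is selected from a 0.5-step grid over (0, 10],
maximising weighted precision, ties to the smaller ratio.  The whole
search is a pure function of (data, config).

The search is **in-sample by design**, as in the original analysis.  At
n = 166 this matters: selection over a few hundred candidate models
inflates the in-sample statistic.  Two consequences are built into the
harness rather than hidden: the acceptance script reports the selected
model's precision on a freshly generated cohort next to the in-sample
value, and a label-permutation run shows that even with no true signal the
in-sample searched precision settles well above the chance level.  For a
label-independent classifier the weighted precision is exactly
`2·p·(1−p)` (≈ 0.479 at 66/100) regardless of its positive-prediction
rate — each class's precision equals its own prevalence — so any excess
over that in a permuted run is pure selection optimism, not signal.

## The synthetic cohort generator

No patient-level data are deposited, so the generator emulates the study
conditions: class sizes 66/100; per-feature Bernoulli prevalences whose
defaults reproduce the direction (and roughly the magnitude) of the
reported per-feature odds ratios — the handful of printed frequencies
(long cord lesions 70%, cord Gd 31%, no cord lesions 11% vs 30%, normal
initial brain ≈ 16%) are matched exactly or by construction, while the
remainder are approximate values back-solved once from reported odds
ratios and marginals; brain T2 totals from negative-binomial families
(dispersion 0.9 / 1.6) whose means are solved so the distribution median
sits centrally at 4 (NMOSD) and 14 (MS), consistent with the printed
ranges; cord lesions as spans with triangular location profiles over the
cervical C2–C6 and mid-thoracic T2–T8 bands (NMOSD) or cervical C2–C7
(MS), long-lesion lengths 6 + Poisson(4) hemi-levels; per-region scan
availability (0.94/0.92/0.27 NMOSD, 1.0/0.86/0.06 MS for
brain/spine/orbits) and relapse-linked scan timing (50% vs 14%).

Derived quantities are generated coherently rather than sampled:
long/short/central/partial/whole/Gd/swelling cord features come from the
actual lesion spans; Paty, Barkhof, nine-or-more and normal-brain come
from the generated counts via the classifier functions themselves; the
implied short-lesion probability is solved from the long and no-lesion
targets (`p_short = 1 − p_none/(1 − p_long)`).  Within-class features are
otherwise sampled independently — the study reports no covariance
structure — with an optional shared latent-severity logit shift, off by
default.  Count-subtype allocation is budgeted within the total so a
subtype count never exceeds the total T2 count; the rare case of a
presence flag with a zero recorded count is allowed (presence may be
observed without a count), while the converse (count > 0 without
presence) is forbidden by the data model.

Randomness uses one master seed with per-patient substreams keyed by
(seed, class, index): enlarging a cohort never reshuffles existing
patients.

**What passing tests do and do not show.**  The generator reproduces
marginal prevalences, count medians, missingness and cord geometry — not
inter-feature correlation, reviewer disagreement, scanner effects, or the
coupling between relapse timing and Gd enhancement.  Pipeline performance
on synthetic cohorts therefore demonstrates correctness of the machinery
and calibration of the marginals, not clinical performance; with
independent features the synthetic classes are, if anything, easier to
separate than real ones (in-sample weighted precision ≈ 0.97–1.0 versus
the reported ≈ 0.94 analogue).

## Problem sizes and tolerances

Calibration checks run at 3,300/5,000 per class over 10 seeds (3 binomial
SE ≈ 0.024 for the 0.70 target, inside the ±0.03 band); search behaviour
is checked at the study's own 66/100 over 10 seeds.  The acceptance script
uses 1,500/1,500 for calibration quantities and 66/100 for the search, and
completes in seconds.  Odds-ratio magnitude checks on sparse features use
wide (factor-of-3) bands because Haldane-corrected estimates on zero cells
are themselves strongly n-dependent.

## Known limitations

* The default score weights and the example decision tree are labelled
  reconstructions; the original fitted artefacts are unpublished.
* No pre-test probability enters any classifier; outputs are
  discrimination labels, not calibrated posteriors.
* The search offers no optimality guarantee (greedy, not exhaustive), and
  no cross-validation — deliberately mirroring the original in-sample
  procedure; the fresh-cohort comparison quantifies the optimism instead.
* Heat-map summary frequencies count any lesion category at a level
  (Gd-only levels cannot occur, as enhancement is modelled as an attribute
  of a T2 lesion span).
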