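# Methods

## Problem and data model

The screen classifies small molecules as CYP1A1 inhibitors or
non-inhibitors from two docking scores per compound: against the
orthosteric (catalytic) site and against a predicted allosteric pocket on
the enzyme's proximal face overlapping the POR-binding interface. Scores
are binding-energy estimates in kcal/mol (more negative = more
favorable). A compound for which the docking engine finds no sterically
valid pose is *bumped* and carries a score of +∞; this is a dedicated
sentinel (`BUMPED`, serialized as `inf`), distinct from missing data,
which ingestion rejects. The allosteric site is promiscuous — nothing is
bumped from it — while the narrow, planar orthosteric site bumps an
appreciable fraction of compounds.

## Reference-set curation

Raw screen records (single-concentration triage flag, winning
concentration–response model, AC50, maximum response, SMILES) are labeled
in a fixed order: (1) compounds overlapping the validation set are
dropped; (2) single-concentration inactives and (3) compounds whose
winning model is the constant are labeled non-inhibitors; (4)
non-constant fits with AC50 > 10 µM or maximum response < 10% are
discarded as ambiguous; (5) the remainder are inhibitors; (6) compounds
with missing/invalid SMILES or fewer than 5 heavy atoms are dropped as
undockable. All bounds are parameters. Inhibitors are banded by AC50:
strong (< 1 µM) or weak ([1, 100) µM). Note the asymmetry between the
10 µM ambiguity bound and the 100 µM weak-band ceiling: the two constants
describe different stages (curation of a screening set vs potency
banding) and are deliberately not reconciled; both are exposed
(`discard_ac50`, the band edges in `assign_potency_band`).

SMILES validity and heavy-atom counts use rdkit when importable;
otherwise a documented regex tokenizer counts element tokens (two-letter
organics first, bracket atoms, aromatic subset). The checker actually
used is recorded in the `CurationReport` so results are attributable.

## Threshold learning

Scores are capped from above before training — allosteric at 0 kcal/mol,
orthosteric at 20 kcal/mol — so bumped (+∞) compounds participate as mass
at the cap. Originals are retained alongside for reporting.

**Constrained grid searches.** A candidate threshold T predicts inhibitor
for score < T (strict `<` everywhere; a score exactly at a threshold
falls on the weaker side). For the orthosteric pair, inhibitor ⇔
score < T_sob or score ≥ T_wob, with T_sob < T_wob, over predicted
binders only. For each search the 95th percentile of all candidates'
balanced accuracies is computed as the linear-interpolation sample
quantile over the full candidate multiset (not distinct values), and the
winner is the candidate with maximum sensitivity among those at or above
it. Ties are broken by higher balanced accuracy, then by the most
negative threshold (lexicographically most-negative-first for pairs) —
the most conservative choice. Both searches are exhaustive over their
grids (61 values; 1596 ordered pairs), so results are exact and
permutation-invariant; tests verify them against independently written
brute-force enumerations.

**Density-valley threshold (T_ob).** The orthosteric score density is
estimated with a Gaussian kernel of standard deviation 3 kcal/mol on a
512-point grid spanning [min − 3·bw, max + 3·bw], matching the
conventional KDE defaults of statistical environments. T_ob is the first
local minimum after the first local maximum, scanning from the most
negative score upward: the valley between the favorable-binder mode and
the bulk. Modes whose density is below 1% of the global peak
(`min_rel_height`, a parameter; 0 restores plain sign-change detection)
are ignored, because a single isolated score under a bandwidth-3 kernel
otherwise registers as its own "first mode" and pulls T_ob tens of
kcal/mol toward the tail — observed on synthetic sets of realistic size.
Between consecutive accepted modes the deepest grid point is taken as the
minimum, so extrema alternate. T_ob is reported at grid resolution; on a
balanced two-Gaussian sample of n = 50 000 the located valley falls
within 0.14 kcal/mol of the analytic midpoint (the KDE of a symmetric
mixture keeps its valley at the midpoint, which is why that closed form
serves as the oracle). A unimodal sample raises an analysis error
suggesting a different bandwidth rather than fabricating a threshold.

## Decision rule and evaluation

The four thresholds partition the (allosteric, orthosteric) plane into
eight regions (strong/weak allosteric × strong/moderate/weak/non-binder
orthosteric). The final rule is a pure function of region: inhibitor iff
(strong allosteric and not moderate orthosteric) or (strong orthosteric).
An orthosteric-only variant (inhibitor iff score < T_ob and outside
[T_sob, T_wob)) is provided for comparison. Evaluation returns the full
confusion table with sensitivity, specificity and balanced accuracy;
region composition reports per-region counts and percentages with the
*category* total as denominator, so the all-inhibitor percentage of a
region is generally not the sum of the strong- and weak-inhibitor
percentages. Reported percentages round half away from zero to one
decimal.

## Kinetics

**Reduction.** Per (substrate concentration, inhibitor concentration):
median over the four technical replicates within each experimental
replicate (robust to single-well outliers), then mean over experimental
replicates; concentration–response ratios divide by the matched 0 µM
inhibitor control, so the control ratio is 1 by construction and the
whole pipeline is invariant to the fluorescence proportionality constant.

**IC50.** The printed two-parameter log-logistic is implemented in its
standard sigmoid form, ratio = 1/(1 + exp(b·(ln[I] − ln IC50))) with
limits 1 → 0 (the algebraic form without the exponential cannot produce a
sigmoid; this is a deliberate correction, noted here). The 0 µM anchor
has no logarithm and is excluded from both fits; the constant model
(ratio ≡ 1) is compared on the same points via AIC = n·ln(RSS/n) + 2k
with k counting fitted parameters plus one for the residual variance
(k = 3 vs 1). A constant winner means no measurable inhibition and
IC50 = ∞; a log-logistic estimate above the highest tested concentration
is censored and displayed as "> max". If the optimizer fails, the
constant model is returned with a warning. Note a structural property of
this selection: the penalty difference of 4 at the 9-point design lets
the log-logistic chase noise on ≈ 10% of truly flat curves, independent
of the noise scale (the RSS ratio is scale-free); a small-sample
correction such as AICc would reduce this but is not what the procedure
specifies, so the plain-AIC behavior is retained and measured by the
acceptance script.

**Michaelis–Menten and mixed inhibition.** V_max and K_m come from a
nonlinear least-squares fit to uninhibited velocities; K_i and α are then
fitted with V_max/K_m fixed (a joint four-parameter refit is available
via `fix_mm=False`; on simulated data the two agree). K_i and α are
fitted on the log scale to enforce positivity, and 95% CIs are Wald
intervals (t quantile, residual degrees of freedom) on the log
parameters, exponentiated — yielding the asymmetric positive intervals
typical of published α CIs. Profile-likelihood intervals are not
implemented. Fits are unweighted by default, matching the conventional
nonlinear-regression workflow; `relative_error=True` weights residuals by
1/v, which is the correct error model when noise is a constant
coefficient of variation (as in the synthetic generator) and brings
empirical 95% CI coverage to 0.94–0.95 in simulation, whereas the
unweighted fit under-covers V_max (≈ 0.85) under CV noise. The MOI rule
uses strict inequalities as printed; α CIs touching exactly 1 or 10 fall
to "mixed".

## Synthetic data

The generators provide the statistical structure the method assumes, with
every parameter in an explicit config and full determinism given the
seed.

*Scores*: 7.8% inhibitors; allosteric scores N(−31, 6²) for inhibitors vs
N(−21, 6²) for non-inhibitors (a ~10 kcal/mol class shift, placing the
learned T_sab in the −20s); inhibitor orthosteric scores an equal-weight
mixture of N(−33, 4²) and N(−10, 5²) flanking a low-density gap, with
non-inhibitors one broad N(−10, 12²) component; orthosteric bump
probabilities 0.05 (inhibitors) and 0.12 (non-inhibitors), allosteric
bump probability 0; strong:weak inhibitor ratio 17:61 with AC50 drawn
log-uniformly within each band. These defaults are illustrative of the
assumed class-conditional shapes, not a replication of any particular
screen: real docking-score distributions are not Gaussian, labels carry
assay noise rather than being exact, and compound structures are absent.
Passing tests therefore demonstrate that the estimators recover the
structure they assume, not that the screen generalizes to real chemistry.

*Kinetics*: fluorescence ∝ the mixed-inhibition velocity with
multiplicative lognormal noise of unit mean at the configured CV (default
5%), over the default design of six two-fold substrate dilutions
(1.56–50 µM), a nine-point inhibitor titration (0–200 µM, three-fold
steps), four technical and two experimental replicates. Default truths
(K_i = 1.4 µM, α = 4.7) correspond to a potent mixed-type inhibitor.
Real plates additionally show edge effects, drift and occasional gross
outliers; only the last is represented (implicitly, via the median
reduction step).

*Activity records*: branch fractions route compounds through every
curation path (triage inactive, constant fit, ambiguous, inhibitor,
missing/short SMILES).

## Problem sizes and verification

The test suite verifies the grid searches against brute-force
enumeration at n = 20 000 (1-D) and n = 5 000 (2-D), KDE valley location
at n = 50 000, K_i/α recovery as the median over 200 simulated assays
(within 15% of truth at the default design), Michaelis–Menten CI coverage
over 500 seeds, and IC50 recovery over 200 seeds — sizes chosen so the
whole suite runs in well under a minute while keeping Monte-Carlo error
small relative to the asserted tolerances.

## Known limitations

- Docking itself is out of scope: the package consumes score tables and
  never computes poses or energies.
- Thresholds carry no uncertainty estimates; the grid searches report
  training-set metrics only, with no cross-validation.
- The decision rule is a hard partition; no probability calibration or
  applicability-domain analysis is attempted.
- The original training and validation score tables are not bundled; the
  two tests that require them fail with an explanatory message unless the
  files are supplied (see README).
- Wald CIs on log parameters can be anti-conservative for weakly
  identified α (very flat inhibition surfaces); the fit warns when α is
  pinned at an extreme value.
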