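# cypscreen

Two-site docking-score virtual screening for CYP1A1 inhibitors, with the
accompanying enzyme-inhibition kinetics analysis.

CYP1A1 metabolizes estrogens, melatonin and arachidonic acid, and is active
in embryonic and fetal tissue; xenobiotics that inhibit it are candidate
developmental toxicants. `cypscreen` implements a tier-one in silico screen
that classifies compounds as CYP1A1 inhibitors or non-inhibitors from two
docking scores per molecule: one against the enzyme's orthosteric
(catalytic) site and one against a surface allosteric pocket on the
proximal face that overlaps the POR (cytochrome P450 oxidoreductase)
binding interface, where a bound ligand can disrupt electron transfer.

## The model

Given a labeled reference set of compounds with docking scores (kcal/mol;
more negative = more favorable; sterically impossible "bumped" poses =
+∞), four decision thresholds are learned:

- **T_sab** (strong allosteric binder): allosteric scores are capped at
  0 kcal/mol and a grid search over T ∈ {−60, …, 0} evaluates the rule
  *inhibitor ⇔ score < T*. Among thresholds whose balanced accuracy
  (mean of sensitivity and specificity) reaches the 95th percentile of
  all candidates', the one with maximum sensitivity is chosen — the
  screen favors sensitivity because inhibitors are rare and hits are
  confirmed experimentally downstream.
- **T_ob** (orthosteric binder): orthosteric scores are capped at
  20 kcal/mol; a Gaussian kernel density estimate (bandwidth 3 kcal/mol)
  of all scores is scanned from the most negative score upward, and T_ob
  is the first local minimum after the first local maximum — the valley
  separating favorable binders from the bulk.
- **(T_sob, T_wob)** (strong/weak orthosteric binder): inhibitor
  orthosteric scores are bimodal with a low-density gap; over predicted
  binders (score < T_ob), a constrained 2-D grid search (T_sob < T_wob,
  both in {−60, …, −4}) evaluates *inhibitor ⇔ score < T_sob or
  score ≥ T_wob*, with the same percentile-constrained
  maximum-sensitivity selection.

The four thresholds partition the score plane into 2 × 4 = 8 regions, and
the final rule calls a compound an **inhibitor** iff it is a strong
allosteric binder that is not a moderate orthosteric binder (score inside
the gap [T_sob, T_wob)), or a strong orthosteric binder regardless of its
allosteric score.

The kinetics half of the package reduces fluorometric activity plates
(median over technical replicates, mean over experimental replicates,
ratio to the 0 µM inhibitor control), estimates IC50 by a two-parameter
log-logistic fit with AIC selection against a constant (no-inhibition)
model, fits the Michaelis–Menten curve v = V_max·[S]/(K_m + [S]) to
uninhibited velocities, then fits the mixed-inhibition model

    v = V_max·[S] / { K_m·(1 + [I]/K_i) + [S]·(1 + [I]/(α·K_i)) }

for K_i and α, and assigns the mode of inhibition from the 95% CI of α:
**competitive** if lower > 1 and upper > 10, **noncompetitive** if
lower < 1 and 1 < upper < 10, otherwise **mixed**.

## Worked example

Train and evaluate on a synthetic reference set with the generator's
default class structure (7.8% inhibitors, inhibitor allosteric scores
shifted ~10 kcal/mol below non-inhibitors', bimodal inhibitor orthosteric
scores flanking a gap):

```sh
$ cypscreen simulate scores --n 1000 --seed 17 --out ref.csv
$ cypscreen train --scores ref.csv --out thresholds.json
INFO thresholds: t_sab=-25.00 t_ob=12.72 t_sob=-25.00 t_wob=-18.00
$ cypscreen evaluate --scores ref.csv --thresholds thresholds.json --report metrics.json
INFO final rule: sens 0.895 spec 0.721
```

The learned strong-allosteric threshold (−25 kcal/mol) sits between the
two class means, the orthosteric pair (−25, −18) brackets the generative
gap, and the final rule recovers 68 of the 76 true inhibitors
(sensitivity 0.895) at specificity 0.721. `thresholds.json` stores the
full candidate tables for audit, and every command writes its resolved
parameters to `<out>.run.json`.

Fit an inhibition assay simulated from a potent mixed-type inhibitor
(true K_i = 1.4 µM, α = 4.7, 5% CV noise, 6 substrate × 9 inhibitor
concentrations):

```sh
$ cypscreen simulate kinetics --k-i 1.4 --alpha 4.7 --seed 17 --out plate.csv
$ cypscreen fit-ki --data plate.csv --out fit.json
INFO K_i=1.51 µM α=3.75 → mixed
```

The estimate K_i = 1.51 µM (95% CI 1.40–1.63) recovers the generative
truth; α = 3.75 with CI 3.14–4.48 falls in the mixed band (lower limit
above 1 but upper below 10), so this single simulated assay is read as
mixed-type inhibition.

`cypscreen curate` labels raw screen activity records into a reference
set, `cypscreen classify` adds region and prediction columns to a score
table, and `cypscreen fit-ic50` runs the dose–response model selection.

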