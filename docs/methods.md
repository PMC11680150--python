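# Methods

## Scope and model

`feedenergy` implements the computational chain of a swine total-collection
energy-balance trial. The biological model is deliberately minimal and
standard: available energy is partitioned as gross energy (GE) minus fecal
losses (giving digestible energy, DE) minus urinary losses (giving
metabolizable energy, ME; gaseous losses are ignored, as is conventional for
growing pigs on cereal diets). Apparent total tract digestibility (ATTD) of
a nutrient is the fraction of intake not recovered in feces; "apparent"
because endogenous secretions are not separated. Energy is MJ throughout;
kcal inputs are converted at ingest with 1 kcal = 4.184 kJ.

Diet-level values carry **no** inclusion correction; the division by the
energy-bearing inclusion (0.974 for a 97.4 % cereal diet) happens only at
the ingredient step. This is the only reading under which diet-level and
ingredient-level summary tables of such trials are mutually consistent, and
it is the convention every result in this package follows.

## Basis algebra

Concentrations and energy densities are either per kg fresh feed (*as-fed*)
or per kg dry matter (*DM*). Conversion multiplies/divides by the DM
fraction. Every profile and result carries an explicit basis flag; mixed-
basis operations raise instead of converting silently. Percentages are kept
on the printed 0–100 scale. The round trip is exact to floating point, and
basis conversion commutes with the linear ingredient-step operations (tested
properties).

## Formulation geometry

A diet is an as-fed inclusion mapping summing to 100 %. Mineral fillers
(premix, limestone, dicalcium phosphate, salt) are modelled as moisture-free,
indigestible, nutrient-free mass by default — trials of this type never
assign them nutrients; an optional filler-ash table can refine diet ash.
Consequences used throughout:

* as-fed energy and organic nutrients mix linearly with inclusion;
* every DM-basis quantity mixes with DM-share weights
  `w_i = f_i·DM_i / Σ f_j·DM_j` (fillers at 100 % DM);
* a nutrient's diet concentration decomposes into per-ingredient
  contributions `c_i = w_i·conc_i`, the algebra both difference-method
  solvers invert.

For the replacement geometry (test ingredient substituting 40 % of a 97.4 %
cereal core), the design closure 0.974 × 0.40 = 0.3896 is validated at
construction.

## Difference method: two readings

The energy-contribution balance ("contribution" mode) solves
`DE_test = (DE_testdiet − w_b·DE_basal_ingredient)/w_t` and is the exact
inverse of the mixing model: a zero-noise simulated trial returns the truth
to ≤ 1e−9 relative, and because the estimator is linear in the mean-zero
multiplicative measurement noise it is unbiased (verified to < 0.5 % of
truth over 500 replicates at 2 % fecal-energy CV).

The "as_printed" mode reproduces the formula as such trial reports commonly
print it, `DE_r = (DE_d − DE_basal·(1 − 0.40))/0.3896` with both diet values
inclusion-corrected by /0.974. Under the trial geometry this equals the
contribution result divided by 0.974 — an internal inconsistency of the
printed formula, which is why the library forces callers to choose a mode
explicitly (the CLI defaults to `contribution` and logs the choice).

For digestibility only the contribution balance is implemented
(`ATTD_test = (ATTD_diet·N_diet − ATTD_basal·c_b)/c_t`); the printed ATTD
difference formula in such reports is internally garbled (symbols that never
recur, one term repeated), so the self-consistent reading is used. Direct-
method ingredient ATTD uses the same balance with a single contributor: for
organic nutrients the cereal carries the nutrient alone and inherits the
diet ATTD unchanged; for dry matter the filler's indigestible share is
divided out.

## Aggregation

Per-diet means are least-squares means of the fixed-effects model
`response ~ C(diet) + C(period)` (statsmodels OLS): each diet's prediction
averaged over period levels, SE from the coefficient covariance, pooled SEM
as the mean of per-diet SEs (identical in a balanced design), and the
diet-effect p from the type-II F test. Period is fixed, not random: with one
observation per pig–period and a balanced Youden rotation, the adjusted diet
means coincide with the mixed-model ones and nothing further is estimable
from these data. Significance is annotated at p < 0.05, tendency at
0.05 ≤ p < 0.10. Connectivity of the diet × period incidence is checked;
disconnected layouts raise an estimability error. Outlier screening reports
within-diet z-scores (|z| > 3 flagged); records are flagged, never silently
dropped (dropping is an explicit pipeline option).

## Correlation and stepwise equations

Pearson r with two-sided p from the t transform (n−2 df), over the
ingredient-level table of composition plus measured DE/ME. Stepwise
selection is classical forward-with-elimination: the candidate with the
smallest partial-F p enters if p ≤ SLE (default 0.15, the long-standing
stepwise default; none is stated for trials of this type), then any entered
variable with p > SLS (default 0.15) is removed, iterating to a fixed point.
Ties in partial F break lexicographically by predictor name, making the
path deterministic. Candidates whose entry would make the design matrix
numerically singular (condition number > 1e10) are skipped with a warning.
The path's R² is monotone in model size, and size-k path models never exceed
— and usually equal — the exhaustive best size-k subset (tested against a
brute-force oracle).

## Synthetic trials

The generator runs the balance arithmetic in reverse. Defaults are the
reference study conditions: 13 diets × 6 periods (cyclic Youden rotation
`diet(pig i, period j) = (i + j) mod t`, one pig column per treatment), body
weight 45.32 kg, feed at 4 % of BW per day, 5-day collection window, and the
bundled 13-cereal truth preset (compositions plus DM-basis DE/ME/ATTD of the
reference panel) so outputs are magnitude-realistic. Per pig × period cell:

    FI   = 0.04·BW·days·DM_fraction·(1 + ε_intake)
    GE_i = FI·GE_diet
    GE_f = GE_i − FI·DE_true·(1 + ε_fecal)
    GE_u = FI·(DE_true − ME_true)·(1 + ε_urinary)
    FO   = FI·(1 − ATTD_DM,true·(1 + ε_fecal'))

with fecal nutrient concentrations consistent with true ATTD, each carrying
its own concentration noise. All noises are multiplicative, mean-zero
Gaussian, truncated by clipping at ±3 CV; a worst-case check at simulation
start guarantees GE_f ≥ 0 and GE_f + GE_u ≤ GE_i for any admissible draw.
Default CVs (fecal 2 %, urinary 5 %, intake 2 %, concentration 3 %) are a
calibration choice that puts simulated diet-level SEMs in the ~0.1 MJ/kg
range typical of real growing-pig balance trials — a plausibility setting,
not a claim about any particular dataset. One master seed governs all
streams; each (pig, period) cell draws from its own deterministic substream,
so output is byte-identical per seed and independent of record order.

What the generator does **not** emulate: refusals/spillage, body-weight
drift across periods, pig-level random digestive efficiency beyond the
per-measurement CVs, or correlated assay errors. Passing recovery tests
therefore demonstrates the *estimators* are correct inverses and unbiased
under this noise model — not that real-trial SEMs or animal variation are
reproduced.

## Reference panel and known irreconcilables

`datasets.py` bundles the 13-cereal reference benchmark (compositions, diet
recipes, diet- and ingredient-level summary values, and four published-style
prediction equations) used for worked examples and as the simulator preset.
Because those summary tables are means whose underlying per-animal records
are unavailable, several cells are documented — and asserted in tests — as
internally irreconcilable rather than reproduced:

* the composition table's starch CV (9.37; the 13 values give ≈15.7) and,
  marginally, its GE CV (4.70 vs 4.66 recomputed);
* the corn 1 diet's as-fed ME (14.72), which exceeds its DE (14.45);
* the DM-basis ingredient energy cells of corn 5, rice 5 and rice 6, which
  are inconsistent with their as-fed counterparts divided by ingredient DM;
* the rice 5/rice 6 ingredient values, which no difference-method reading
  maps onto the bundled diet means at printed precision;
* the bundled equation coefficients and the DE–starch correlation (0.84
  carried vs ≈0.56 recomputed from the DM-basis means), which cannot be
  refit from the 13 ingredient means on either basis — the per-observation
  data behind them were never released.

The diet recipes list corn 5 as the basal cereal of the rice 5/6 replacement
diets, following the stated design, although some summary layouts line the
58.44 % inclusion up with the corn 1 row.

## Numerical choices

* Sample SD (n−1) everywhere; CV = 100·SD/mean, undefined at zero mean
  (raises), scale-invariant by construction.
* Report rounding is half-up (away from zero) to 2 decimals, matching
  printed-table convention; machine outputs are unrounded.
* Zero-noise recovery tolerance 1e−9 relative; serialization of equation
  registries uses `repr` floats for bit-exact round trips.
* Physically impossible records (outputs exceeding intake) are flagged with
  a validation report and retained; negative difference-method estimates are
  flagged and returned, never truncated.

## Problem sizes used in the validation suite

Zero-noise round trips and recovery checks run the full 13 × 6 design
(78 records). The difference-method bias check uses 500 replicates at 2 %
fecal CV with a direct per-diet-mean recovery path. The stepwise oracle
comparison uses 100 random Gaussian instances at n = 50 with 6 candidates;
the coefficient-recovery check uses n = 200. The LSMeans coverage property
uses a 6 × 4 rotation over 200 seeded replicates and asserts the ~95 %
nominal 2·SE coverage above its 4-sigma binomial lower bound (0.93), so the
test fails on estimator error, not on sampling luck.
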