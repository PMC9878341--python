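# Methods

## The model

`prediabn` models the 5-year progression from prediabetes to type 2
diabetes (T2D) with a discrete Bayesian network over 12 categorical
variables: GENDER, T2D, SOCIALs (social status I–III), SMOKING, PA
(physical activity ≥150 min/week), DIET (daily fruit/vegetables), HbA1c
(dichotomised at 6.0%), FLI (fatty liver index, cut at 30 and 60), BMI
(WHO categories), BP (blood-pressure grades), TG (triglyceride bands) and
AGE (three intervals).  A network B = (G, θ) couples a DAG G with one
conditional probability table (CPT) per node and encodes the joint
distribution by the chain rule P(x₁…x₁₂) = Π P(xᵢ | pa(xᵢ)).  All
reasoning — risk ranking, trajectories, what-if scenarios — is exact
posterior computation on this factorisation.

## Structure learning

The DAG is learned by greedy hill climbing on a decomposable score,
starting from the empty graph and applying the best single arc addition,
deletion or reversal until no move improves the score.  The score is the
Akaike Information Criterion in "higher is better" form,
`AIC = logL̂ − Σᵢ (rᵢ−1)qᵢ` (rᵢ states, qᵢ parent configurations).  The
−2-scaled variant would have the same argmax; the convention is fixed
here and matters only when comparing raw scores.

Expert knowledge enters as an ordered partition into four blocks —
background {GENDER, AGE, SOCIALs}, lifestyle {DIET, SMOKING, PA, BMI},
clinical {HbA1c, FLI, BP, TG}, diagnostic {T2D} — and every arc from a
later to an earlier block is blacklisted (51 forbidden arcs for these
block sizes).  Arc support is assessed by nonparametric bootstrap model
averaging: the learner is re-run on R resamples of size n drawn with
replacement, each arc's strength is its inclusion frequency (in either
direction), and arcs with strength ≥ 0.85 (inclusive), oriented by
majority direction, form the consensus network.  Defaults are R = 500 and
threshold 0.85.  Numerical choices: candidate moves are enumerated
pair-major in variable declaration order (add, delete, reverse within a
pair), a move needs strict improvement > 1e-9, direction ties (exactly
0.5) orient from the earlier-declared variable, and a cyclic consensus is
repaired by dropping the weakest conflicting arcs.  Random restarts are
available but off by default; a single greedy run is the canonical
procedure.

Because likelihood-equivalent DAGs can swap within-block arc
orientations without changing the score, structure recovery in the test
suite is judged on the undirected skeleton; orientation is reported via
the direction probabilities of the strength table.

## Parameter learning

For a fixed DAG, CPTs are posterior means under a uniform Dirichlet
prior with equivalent sample size `iss`:
θ̂ᵢⱼₖ = (nᵢⱼₖ + iss/(rᵢqᵢ)) / (nᵢⱼ + iss/qᵢ).  The default iss = 1 (one
imaginary observation spread over all cells) is the conventional choice
when the source analysis states only "Dirichlet"; iss is configurable,
iss → 0 recovers maximum likelihood where data exist, and iss = rᵢqᵢ is
Laplace add-one.  Every estimate is strictly positive, so fitted networks
never assign a held-out record zero probability.

## Inference

Posteriors are computed by variable elimination with a min-degree
elimination heuristic; the order affects cost only.  Factors are carried
in linear space — with 33 states across 12 variables the largest
intermediate tables are tiny, and the full joint (124,416 cells) can be
enumerated outright, which the tests use as an oracle.  Should the
package be applied to models with hundreds of states per clique, factor
tables should move to log space; that threshold is far from this domain.
Evidence with normalisation constant ≤ 1e-300 raises an explicit
inconsistent-evidence error.

## Risk analyses

* **Markov-blanket ranking** — for each variable in the blanket of T2D
  (its parents, children and spouses; here PA, AGE, BMI, FLI, HbA1c),
  find the state maximising P(T2D = Yes | V = s) and rank variables by
  that maximum.  Ties in the maximising state go to the earlier declared
  state; ranking ties break alphabetically.
* **Stepwise trajectories** — evidence is instantiated cumulatively along
  a fixed plan; step k's value equals an independent posterior call with
  the union of the first k observations.  The six published figure plans
  ship as YAML data files (`age_first`, `bmi_first`, `pa_first`,
  `fli_first`, `hba1c_first`, `diet_intercausal`) so the analyses rerun
  verbatim.
* **Scenario comparison** — named evidence sets, including variables
  outside the blanket (intercausal reasoning); the same posterior
  machinery applies with no special casing.

## Validation

10-fold cross-validation (seeded random partition, no stratification)
re-runs the full pipeline per fold — blacklist, hill climbing, Bayesian
fitting — and reports the mean negative natural-log joint probability
per held-out record.  For data drawn from a known network this loss is
bounded below by the generating joint entropy (computable exactly here by
enumeration), which is the yardstick the tests use.  Per-feature scores
predict each variable from the other eleven on held-out records:
one-vs-rest AUC per state (midrank ties) using the posterior probability
as score, and argmax accuracy per variable.  P(V | rest) is evaluated in
closed form from the families containing V; by the global Markov property
this equals the full-evidence variable-elimination posterior (asserted in
the tests).  Held-out per-record posteriors can be exported for external
classifier comparisons; no third-party classifiers are bundled.

## The synthetic cohort

The study cohort (Spanish working adults with prediabetes, n = 16,648;
12,080 men) is not publicly deposited, so the package ships a calibrated
ground-truth network and samples synthetic cohorts from it.  Its DAG is
the reported 28-arc structure (roots GENDER, SOCIALs, SMOKING; e.g.
Pa(T2D) = {PA, AGE, BMI, FLI, HbA1c}).  The AGE CPT is the published
age-by-gender-and-social-status table verbatim; two of its printed rows
sum to 0.9999/1.0001 and are renormalised (entries unchanged to four
decimals).  The GENDER marginal is 12,080/16,648.  SOCIALs (0.22, 0.46,
0.32) and SMOKING (0.47, 0.22, 0.31) marginals are unpublished and were
fixed once at values plausible for a working-age Spanish population.

All remaining CPTs start from additive log-linear ("softmax") scores
whose per-parent effects encode the expected epidemiology — adiposity,
high TG, poor diet and inactivity push FLI up; adiposity, fatty liver and
age push HbA1c up; all five parents of T2D raise conversion risk in their
adverse states — with every arc given a clearly nonzero effect so the
dependency structure is statistically visible at cohort sample sizes.
Calibration then adjusts a set of one-parameter multiplicative "knobs"
(state-odds tilts, per-parent effect tilts, and a few interaction tilts)
until exact inference matches every published probability: seven
marginals (±0.005) and five single-evidence conditionals of T2D (±0.01).

Two published inconsistencies are handled rather than resolved: the PA
split is printed as 40.4% practice / 58.6% no practice (sums to 99.0%);
the no-practice value is calibrated to.  And the printed values
P(HbA1c<6) = 0.633, P(T2D=Yes | HbA1c>6) = 0.635 jointly force
P(T2D=Yes) ≥ 0.233, whereas 0.223 is printed — the targets are only
jointly satisfiable at the edges of their tolerance bands, with
conversion at normal HbA1c driven nearly to zero.  This has two
consequences.  First, the calibration objective is a soft-margin
(hinge) residual per target, flat inside the tolerance band: plain
squared error would prefer one out-of-band target over several in-band
ones and miss the feasible corner.  Optimisation is coordinate descent
with bounded exact line searches (descent-only acceptance; the objective
trace is non-increasing), alternated with a joint least-squares
refinement over all knobs, because axis-aligned moves approach narrow
corners slowly; a final centering pass then re-balances the solution
away from the band edges (minimising the headline marginal's tolerance
utilisation subject to soft walls at 95% of every band), since the hinge
exerts no force on a target parked at exactly 100% of its tolerance.
Second, the packaged network necessarily understates
conversion among normal-HbA1c subjects relative to some other figures in
the source (which are not calibration targets); interaction knobs encode
this "HbA1c gates conversion" pattern.

The calibrated network is frozen as package data
(`data/ground_truth_network.json`); `calibrate_ground_truth()` re-runs
the construction for audit and is never executed at import time.

**What the generator does and does not emulate.**  It reproduces the
published structure, the AGE table, and twelve printed probabilities, and
its effect directions follow the epidemiology described above.  It does
not reproduce the real cohort's unpublished higher-order interactions,
measurement error, or selection effects; passing recovery tests therefore
demonstrates correctness of the learning machinery under a faithful,
known generator — not performance on the real data.  Unpublished
magnitudes (e.g. the diet effect on conversion) carry the correct sign
but not necessarily the printed size.  One calibration side-effect is
visible in structure recovery: because the feasible corner makes
conversion HbA1c-gated, the direct FLI→T2D effect is small and that arc
sits near the 0.85 averaging threshold at the test's 50k scale; the
consensus network typically recovers 27 of 28 skeleton arcs.

## Test problem sizes

The suite exercises recovery at sizes chosen to keep the default run
comfortably on one CPU: structure recovery uses three 50,000-record
cohorts with 100-replicate averaging (a scaled-down stand-in for the
500-replicate production default — inclusion frequencies at 100
replicates already resolve the 0.85 threshold well); parameter recovery
uses 200,000 records; cross-validation uses the study's n = 16,648.
Maximum-error CPT claims are made only for well-supported tables (the
AGE rows); elsewhere the tests use population-weighted total-variation
error, since parent configurations with vanishing probability receive no
data at any realistic n and stay at the prior mean.

## Known limitations

* Fully discrete networks only; no conditional-Gaussian or temporal
  extension.
* Complete-case analysis: a missing-value marker is tolerated in tables
  but every learning/validation operation rejects it explicitly.
* AIC is the only built-in structure score (a pluggable interface exists);
  constraint-based learners are out of scope.
* The BIF reader is read-only and covers the classic discrete dialect.
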