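# Methods

`casecross` implements a time-stratified case-crossover analysis of
short-term fine-particle (PM2.5) exposure and daily mortality, with effect
modification by a decedent's race and by census-derived measures of their
block group's racial composition and residential segregation. This note
records the statistical model, the conventions and numerical choices the
package fixes, what the synthetic-data generator does and does not emulate,
and known limitations.

## Design and likelihood

Each death defines a *matched set*: the case day (date of death) plus
referent days chosen every 3rd day before and after the case day within the
same calendar month and year. These strata are fixed calendar partitions —
all days of a month sharing a day-of-month residue mod 3 — so referent
selection is symmetric within the stratum, the property that removes the
overlap bias of unidirectional referent schemes. Every calendar day yields
8–10 referents (8 only in 28-day Februaries for mid-cycle days).

With design row `x_j` for day `j` of a set, the conditional logistic
log-likelihood is

    l(beta) = sum_sets [ x_case·beta − log sum_{j in set} exp(x_j·beta) ],

a softmax probability of the case day among the set's days. Covariates
constant within a set cancel. This has two practical consequences the
package enforces:

* **Modifier main effects are structurally inestimable.** Race, percent
  black, RRS and IRD are person/place attributes, constant across a set's
  days; only their *interactions* with the time-varying exposure enter the
  design. A set-constant column raises `RankDeficiencyError` naming it,
  rather than producing a silently singular fit.
* The likelihood is invariant to adding any set-constant vector to a set's
  covariate rows (verified to 1e-10 relative — exact bitwise equality is not
  attainable because offsets enter `X·beta` before the per-set
  log-sum-exp stabilization).

The analysis model contains the exposure window (two-day mean PM2.5, lags
{0,1}; single-lag windows are configurable), six day-of-week indicators with
Sunday as reference, and linear + quadratic terms of same-window
temperature. Temperature is centered at its sample mean before squaring;
this only reparameterizes the temperature coefficients and leaves the
exposure estimate unchanged (tested), while reducing collinearity between
the linear and quadratic terms.

## Exposure assignment

Each record is assigned, once, the series of the grid cell nearest its
residential coordinates — a static-residence assumption. Distance is
great-circle (haversine, mean Earth radius 6371.0088 km); at 1-km grid
spacing the difference from planar distance is negligible but one convention
must be fixed. Ties are broken by smallest cell id so assignment is
deterministic and permutation-invariant. The vectorized path uses a KD-tree
on unit-sphere coordinates: chord distance is monotone in great-circle
distance, so the query is exact; near-ties are re-checked among the closest
candidates with the same tie-break.

A window mean is defined only when every constituent daily value exists.
Missing days are excluded, not imputed: a missing referent day drops that
day, a missing case day drops the whole set (imputation would distort the
within-set exposure contrasts that carry all the information). Counts of
dropped days/sets are logged.

## Segregation indices

* **RRS** (racial residential segregation score), a concentration-at-the-
  extremes form: `(n_white − n_black) / n_total`, in [−1, 1]; negative means
  black-majority. Zero population makes the score undefined — such block
  groups are flagged and excluded, never coerced to 0. For categorical
  analyses the score is binned G1=[−1,−0.5), G2=[−0.5,−0.1), G3=[−0.1,0.1],
  G4=(0.1,0.5], G5=(0.5,1]; half-open edges make the bins an exact partition
  (published category boundaries overlap at the endpoints), and G1 is the
  reference level.
* **IRD** (index of racial dissimilarity): the classical dissimilarity index
  of a tract's block groups, `D = 50·Σ|b_i/B − w_i/W|` in percent, assigned
  to every block group of the tract. The tract-level form attains the full
  0–100 range (a leave-one-out "local" variant caps at 50%). A tract with a
  zero black or white total makes D undefined — flagged and excluded.
* Percent white/black use total population (all races) as denominator.
* A single census table (one vintage) is used for all study years.

## Fitting

Newton–Raphson with step-halving, started at 0, at most 50 iterations,
convergence when the gradient max-norm is below 1e-8 *in standardized
coordinates*: each column is internally scaled by its within-set standard
deviation (a pure reparameterization) so that the tolerance is meaningful
when columns differ in scale by orders of magnitude (e.g. exposure ×
percent interactions). A second stopping rule handles the float64 floor:
when the Newton decrement (the predicted log-likelihood gain of the next
full step, `gᵀH⁻¹g/2`) falls below 1e-12 — beneath the rounding resolution
of a log-likelihood of magnitude ~1e4 — the optimum is resolved to machine
precision and the fit is declared converged even if the gradient norm,
itself a difference of large sums, has plateaued slightly above the
tolerance. Estimates and covariance are returned on the
original scale; the covariance is the inverse negative Hessian at the
optimum. Gradient and Hessian are the exact analytic derivatives;
per-set log-sum-exp uses max-subtraction so the likelihood is finite for
any finite coefficients.

Monotone likelihood (separation) is declared when a standardized
coefficient exceeds 8 — a per-standard-deviation odds ratio above e^8 does
not occur in estimable data of this kind — and raises `SeparationError`
naming the column. Rank deficiency of the within-set-centered design is
detected by pivoted QR and names the collinear columns.

## Reporting

Per-unit log odds `b` are reported as percent change per Δ = 10 μg/m³:
`PC = 100·(exp(Δ·b) − 1)`, CI from `b ± 1.96·se`. Effects at a modifier
value `m` use `b(m) = b1 + m·b2` with the delta-method standard error
`se(m) = sqrt(v11 + m²·v22 + 2m·v12)`; re-centered refits would give the
identical point estimate, the delta method needs no refitting. Continuous
modifiers are summarized at their 10th/50th/90th percentiles over
*decedents* (one value per matched set; nearest-rank convention,
`ceil(p·n/100)`), since the reported anchor percentiles describe the
decedent-weighted distribution. For the five RRS categories the per-level
effect adds the level's interaction coefficient to the exposure
coefficient, with the delta-method se from the 2×2 covariance block and a
per-level Wald p against G1; no multiplicity adjustment is applied across
modifiers or levels. The below-NAAQS sensitivity restriction removes days
whose *daily* (lag-0) PM2.5 exceeds 35 μg/m³; a set is dropped when its
case day is removed or no referents remain (the published description —
"periods below the standard" — is ambiguous between day-level and
stratum-level exclusion; day-level with case-day drop is the convention
fixed here).

## Synthetic-data generator

The generator produces the three study inputs under a known-truth Poisson
log-linear daily death rate per (block group, race):

    lambda = n_at_risk · base_rate · exp( dow + b1·T_c + b2·T_c²
                                          + beta·PM_w + delta·PM_w·m )

with `PM_w` the two-day-window PM2.5 and `m` the configured modifier
(block-group percent black, decedent race, or any scored column). Because
deaths are rare at this scale, conditioning the Poisson counts on the
stratum totals yields exactly the conditional-logistic softmax with
exposure log odds `beta + delta·m`, so the pipeline's estimand equals the
echoed truth by construction — the reason a Poisson mechanism was chosen
over per-person Bernoulli draws (exact estimand control at tractable
runtime).

What it emulates, and the default values (all configurable):

* **Race composition.** Percent black per block group is a four-part
  mixture: a point mass at exactly 0 (25% of block groups), a right-skewed
  low-mix bulk (Beta with a = 0.9; its b is *solved at run time* so the
  distribution's 90th percentile hits the configured anchor of 16%), a
  small high-black component (4%, Beta(8,2)) and a small racially balanced
  component (3%, Beta(25,27)) so that all five RRS categories are populated.
  The p10 = 0% anchor requires at least 10% exactly-zero block groups;
  infeasible anchor settings raise a validation error. Another few percent
  belong to other races (Beta(2,30)), so `n_white + n_black ≤ n_total`.
  Block-group populations are uniform on [600, 3000], the census sizing of
  a block group. Percentiles are anchored block-group-weighted, which
  coincides with the decedent-weighted distribution in expectation because
  the baseline rate is per capita.
* **PM2.5** (μg/m³): base 10, annual cycle (amplitude 2.5), shared regional
  AR(1) with lag-1 coefficient 0.6 and stationary sd 6 — day-to-day
  variation typical of daily urban PM2.5 and the within-stratum contrast
  the design estimates from — plus a time-constant cell offset of
  0.03 μg/m³ per percent black (the exposure-disparity gradient) with sd
  0.8 of unexplained cell noise, plus iid daily cell noise (sd 1), truncated
  at 0.
* **Temperature** (°C): mean 10, annual amplitude 12 (winter trough late
  January), AR(1) 0.7 with sd 3, small cell noise.
* **Mortality**: per-capita base rate 3.2e-5/day (≈21,000 events over the
  default two years × 500 block groups — per-block-group event counts of
  the same order as the real study's 288 per block group over 11 years);
  true exposure effect ln(1.02)/10 per μg/m³ (2% per 10 μg/m³); day-of-week
  log-multipliers within ±3%; U-shaped temperature term (−0.005/°C linear,
  +0.0004/°C² quadratic around 15 °C). Decedent race is drawn by splitting
  the rate across the block group's white/black counts; ages, sex,
  education and place of death are descriptive only, with race-specific age
  distributions.
* One master seed drives three spawned child streams (census, exposure,
  events); identical seeds give bit-identical output.

Not emulated: spatial covariance of PM2.5 beyond the shared regional signal
plus per-cell offsets; exposure measurement error; residential mobility;
mortality displacement; within-block-group sociodemographic confounding.
Passing recovery tests therefore demonstrate correctness of the estimator
under the design's own assumptions — not robustness to exposure error or
model misspecification in real data.

## Simulation-study conventions

Parameter-recovery and coverage studies run at the default scale
(500 block groups, 2 years, ~21,000 events per replicate), holding the
geography (census draw) fixed across replicates while exposure and events
are redrawn; type-I-error replications use a reduced scale (150 block
groups, 1 year) to afford 400 replicates. Replicate seeds are spawned from
one master seed. The full-scale configuration mirroring the real study
(4,613 block groups, 11 years, ~130k events) is provided as
`FULL_SCALE_CONFIG` for users who want study-sized runs.

## Known limitations

* Inference is Wald/normal throughout; set counts in intended applications
  are 10^4–10^5, where this is appropriate. No exact conditional inference
  for sparse strata.
* The NAAQS restriction is applied to the lag-0 daily value; restricting on
  the window mean is possible by passing that column explicitly.
* The dissimilarity index inherits the classical index's insensitivity to
  the spatial arrangement of block groups within the tract.
* Continuous-modifier interaction tests are single-coefficient Wald tests;
  no joint 4-df test across RRS categories is provided.
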