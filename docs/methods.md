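# Methods

## The model

`costmin` implements a cost-minimisation analysis (CMA) of store-and-forward
teledermatology against conventional dermatology referral, from a societal
perspective. A CMA compares only costs, on the premise that health outcomes
are equivalent between the alternatives; the costing horizon is one care
episode, from GP referral to six months after referral, with no discounting
(the horizon is under a year).

Each arm's episode cost is a sum of cost components in five societal
categories:

* **investment** — digital camera, web application, training (tele arm
  only), depreciated over 3 years × 60 episodes per GP per year;
* **GP care** — consultation time × €/min, plus (tele arm) teleconsultation
  activities, a share of diagnostics/treatment, and follow-up;
* **dermatologist care** — first and follow-up consultations × €/min (rate
  weighted 10% teaching at €5.6/min, 90% non-teaching at €6.7/min → €6.59),
  diagnostics/treatment, and (tele arm) the teleconsultation itself;
* **out-of-pocket** — travel at €0.25/km, parking €2.5 per hospital visit,
  an accompanying person for 20% of visits;
* **employer** — productivity loss: visit time (consultation + travel +
  waiting) × €35/h × a work-participation share.

The key coupling parameter is the preventable proportion *p* (point value
0.20, distribution β-integral(4, 19)): in the tele arm the dermatologist
first visit, follow-up, diagnostics/treatment, hospital travel and
hospital-visit employer time all scale by (1 − *p*), while GP
diagnostics/treatment, GP follow-up, GP travel and GP employer time scale
with *p*. The tele-arm dermatologist first visit is additionally shortened
by a factor (1 − share × magnitude) with share 0.14 and magnitude 0.10
(sampled β-integral(3, 30); the source's "n = 3, r = 30" is transposed, as
r < n is required and the mean 0.10 matches the stated 10% shortening).

Components are arithmetic expressions over parameters in a deliberately
total language (constant, parameter reference, add, subtract, multiply).
Division is excluded so sweeps can never hit a zero denominator; the one
place a sampled parameter appears in a denominator (the website cost
divisor 1/(3 yr × accounts × 60 episodes)) is re-expressed as a
reciprocal-rate parameter with a triangular distribution on the transformed
range — a reconstruction, since triangular uncertainty on a reciprocal is
not the same as on the original scale.

## Two reference profiles

The original study model had 282 variables; only a headline subset of
parameters and the per-category cost table are published. No single model
built from the published subset can reproduce both. The package therefore
ships two profiles.

### Mechanistic profile

Assembled bottom-up from the published primitives with the formulas above.
Its point totals (tele €413.2, conventional €374.1, incremental €39.1)
differ from the published means; every discrepancy is written to the build
log (`costmin build-reference`). Use this profile for *structure*: the
direction of scenario effects, break-even existence, importance ranking.
Two values are explicit parameters the source leaves unstated: the
work-participation share (0.33, chosen so the conventional employer cost
matches the published ≈ €47.3 — the source says only that participation
resembles national averages) and travel time (1.5 min/km, i.e. 40 km/h),
which couples visit time to distance so that distance sweeps move employer
costs; without that coupling the hospital-distance sweep could not cross
zero. GP and dermatologist follow-up durations default to one standard
consultation (8.1 and 10 min).

### Calibrated profile

One component per (arm, category). The constant terms are the published
category means; the tele out-of-pocket constant is 12.2 (= 16.3 − 4.1)
where the published table prints 12.4 — the table's own rows are
inconsistent by €0.2 (and its totals by €0.5: 387.0 − 354.0 ≠ 32.5), and
the incremental column is taken as authoritative because the headline
incremental €32.5 is its sum.

Uncertainty is an additive latent-factor design over independent standard
truncated-normal parameters (±5 σ):

    conv_cat = μ_cat + σ_cat · (λ·W + √(1−λ²)·Z_cat)
    tele_cat = conv_cat + δ_cat + b_cat·S + t_cat·E_cat [− k·Z_derm for dermatologist]

where each published 95% interval is converted to a standard deviation
(width / 2·z₀.₉₇₅), λ = 0.5 is a shared level factor W reproducing the
positive cross-category correlation implied by the published
conventional-total interval being wider than an independent sum, and S is a
care-shift factor loading positively on the GP incremental and negatively
on the dermatologist incremental. The S loadings are solved from the
published total-incremental interval (−29.0, 74.7): independent category
increments would give SD ≈ 29.6 €, the published total implies 26.45 €, so
the GP and dermatologist increments must be negatively correlated — exactly
the mechanism *p* induces in the mechanistic profile. A cross term −k·Z_derm
matches the published tele-dermatologist interval, which is *narrower* than
the conventional one. All loadings are closed-form functions of published
interval widths; nothing is fitted to simulation output.

What this calibration matches exactly (at the Gaussian approximation):
category means, conventional-category and incremental-category interval
widths, the tele-dermatologist width, and the total-incremental mean and
SD — hence the ≈ 0.89 probability that conventional care is cheaper. What
it matches only approximately: the arm-total interval *endpoints* (within
~6%, tested at a 10% fidelity tolerance) and the skew of individual
published intervals — the latent design is symmetric, while some published
intervals (employer, investment) are visibly skewed. The published
investment interval (mean 1.6, CI 1.6–2.1) is internally impossible for
any distribution with that mean and is represented by its width only.

## Probabilistic sensitivity analysis

Second-order Monte Carlo with 10,000 draws by default. Every parameter
flagged for uncertainty analysis draws from its own deterministic substream
(SHA-256 of root seed + parameter id → generator seed), so draws are
reproducible, prefix-stable in n, and insensitive to adding or removing
other parameters. Parameters are sampled independently; between-arm
correlation arises only through parameters shared by both arms' expressions.
Summaries come from the stored draws: percentile intervals (midpoint
interpolation), the probabilities that each arm is cheaper (exact ties
counted separately), and a 50-bin histogram of the incremental cost over
the observed range. The analytic companion `prob_positive_gaussian` treats
a (mean, 95% CI) pair as Gaussian and returns P(> 0) — the independent
oracle for the simulated probability.

## Scenario analysis and break-even

Sweeps are deterministic: the model is evaluated at point values with one
(or two) parameters overridden over a grid, vectorised through the
expression evaluator. Break-even search pre-scans 64 points for sign
changes and bisects each bracket to a tolerance of 1e-3 parameter units by
default; all roots are returned sorted (published scenario curves are
monotone, synthetic models need not be). Two-way sweeps report the zero
contour as per-row break-even values of the second parameter.

## Importance ranking

OLS regression of the per-draw incremental cost on the sampled parameter
draws, both z-scored (n−1 denominator); ranking by |standardized
coefficient|, ties broken by parameter id. Zero-variance (point-mass)
parameters are excluded and reported as such; rank deficiency (fewer draws
than covariates + 1) raises rather than silently regularizing. No
interactions and no stepwise selection. Composite published parameters
(e.g. "teleconsultation activities", elicited as nine sub-activities) are
represented by their aggregate draw.

## Synthetic models

`costmin.synthetic` generates random valid model definitions for property
testing: parameter values log-uniform in [0.1, 100] (matching the three
orders of magnitude between €0.25/km and €40k in real unit costs), a
configurable point/triangular/beta mix, and random expression trees whose
point totals are book-kept independently during emission. Two structured
generators carry analytic oracles: a linear-PSA fixture whose standardized
coefficients are known in closed form (cᵢ/√(Σc² + σ²_noise)), and a
monotone break-even model with a known root. These fixtures are synthetic
by construction: they emulate structural validity and scale heterogeneity,
not realistic clinical cost structure, so passing property tests shows the
machinery is correct, not that any particular clinical model is.

## Numerical choices and problem sizes

* Fixed summation order (components lexicographic by id, categories in
  declaration order) makes breakdowns bit-reproducible; the conservation
  identity (arm total = Σ categories, incremental = tele − conv) is exact
  in that order.
* Default PSA size 10,000 draws matches the study design; distribution-mean
  convergence checks use 100,000 draws; the bisection-vs-grid-scan property
  uses 100 random models against a 10,001-point scan. The test suite and
  acceptance script together run in well under a minute on one CPU.
* Monte Carlo agreement tests use 3-standard-error bands; calibration
  fidelity of simulated arm-total interval endpoints is tested at 10%
  relative tolerance.
* Not in scope: reproducing the study's printed break-even values (37%
  preventable, 75.1 km, 2.1 minutes, €353.3, €465.7). These depend on the
  unpublished full model's couplings; the mechanistic profile reproduces
  their existence and direction (its hospital-distance break-even lands at
  ≈ 62 km), and the tests assert exactly that.

## Known limitations

* The calibrated profile is a statistical surface, not a mechanism: its
  latent factors reproduce published moments but carry no clinical meaning.
* Symmetric latent factors cannot reproduce the skew of individual
  published intervals; the tele out-of-pocket and employer interval widths
  inherit small inconsistencies from the published table itself.
* Independent sampling (no copulas, no Latin hypercube) and a two-arm
  limit are deliberate scope bounds, as are the absence of QALYs/effects
  (this is cost-minimisation, not cost-utility) and of any discounting.
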