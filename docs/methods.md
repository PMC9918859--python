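# Methods

This note documents the models, the synthetic-data generator and the
numerical choices behind `boxvisits`, in the spirit of a statistical
methods appendix.

## Territory geometry

Territories are Thiessen (Voronoi) polygons around the occupied
breeding boxes of one season, clipped to the study area. The study
area defaults to the convex hull of all boxes buffered outward by half
the mean nearest-neighbor spacing: unbounded edge cells must be clipped
somewhere, and this buffer keeps edge territories finite without
distorting adjacency among interior cells. Any other polygon can be
supplied. Coordinates are planar meters throughout; geographic input
must be projected upstream (the emulated site is < 1 km across, so a
local projection is exact for all practical purposes).

*Neighborhood order* between two territories is the shortest-path
length in the adjacency graph whose edges connect cells sharing a
border of positive length (tolerance 1e−6 m). Point contacts — as
between diagonal cells of a perfectly regular grid — are **not**
adjacency; synthetic layouts are jittered, so cocircular degeneracies
do not arise in practice. Territories in disconnected components get a
distinguished non-numeric "unreachable" value rather than a number.
Every box (occupied or not) is assigned to the territory of its nearest
occupied box; exact ties go to the smallest territory id and are
logged.

## Visit processing

A "visit" is a maximal run of readings by one individual at one box in
which consecutive readings are separated by at most the merge window
(default 10 min). The window is interpreted as an inter-reading gap,
not a fixed-width bin anchored at the first reading: gap-based
sessionization is the standard event-stream semantics and does not
split continuous bouts arbitrarily. A visit's day is the calendar date
of its first reading. Identical (individual, box, timestamp) rows are
deduplicated before merging; unparseable timestamps are dropped and
logged.

Inclusion rules retain extra-territorial visits by breeders whose
attempt fledged, made between the start of nest building and fledging
(both inclusive), by birds tagged on or before nest building. Failed
breeders contribute no visits at all — neither before nor after
failure — because territoriality may break down after failure and
keeping only pre-failure visits would over-represent early breeding
stages. Every rule is evaluated independently of the others, so the
retained set cannot depend on rule order; the manifest reports both a
first-rule partition (counts sum to the number excluded) and per-rule
overlapping counts.

## Mixed models

All responses are binary, fitted as logit-link GLMMs with independent
crossed random intercepts. The fitter maximizes the Laplace
approximation to the marginal likelihood — the approximation
`lme4::glmer` uses at `nAGQ = 1` — in two stages: a fast profile over
the random-effect scales with fixed effects held at the joint penalized
mode (equivalent to `nAGQ = 0`), then a bounded quasi-Newton refinement
of (σ, β) jointly with only the random-effect modes profiled, which
honors the β-dependence of the log-determinant term. One test verifies
agreement with `glmer` on estimates, standard errors and variance
components to two–three decimals. When every variance estimate
collapses to zero the fit equals ordinary logistic regression (checked
against a closed-form 2×2 odds ratio and against `statsmodels`).

Numerical settings: inner Newton on the penalized log-likelihood with
step halving, gradient tolerance 1e−11 relative (the log-determinant is
linear in mode error, so the inner solve must be much tighter than the
outer tolerance); outer L-BFGS-B with finite-difference step 1e−6,
variance scales bounded in [0, 15]; linear predictors clipped at ±30 to
keep separated fits finite. Fits are deterministic given data and
specification. A grouping factor with a single level is dropped with a
warning (a one-season table cannot estimate a year variance).

Wald z and two-sided normal p-values are reported for all fixed
effects; no multiple-testing correction is applied. Standard errors
come from the inverse joint penalized Hessian at the optimum,
conditional on the variance estimates, as in `lme4`.

Date, neighborhood-order and distance covariates enter through
orthonormal polynomial bases of degree 2 computed on the observed
values with unit-norm columns (as R's `poly()`); this removes the
severe collinearity of raw powers and is why quadratic estimates are
orders of magnitude larger than raw-unit slopes. A raw basis would
change the printed scale, not the fitted curves.

**Separation.** A fit is flagged when any standard error exceeds 50,
or when a *raw-scale* estimate exceeds 15 in magnitude. The magnitude
heuristic deliberately exempts orthonormal-basis columns: unit-norm
basis coefficients are legitimately in the tens to hundreds, so
applying the raw threshold there would flag every seasonal model. A
flagged fit is still returned — tiny disperser samples genuinely
produce quasi-separated fits, and the flag (not an exception) is the
faithful representation of that situation. A covariate that is
perfectly constant in a tiny subgroup model makes the design
rank-deficient; the model battery logs and skips such a fit rather than
failing the run.

**Daily probability profiles** refit the model with date as a factor
(one level per day, no intercept) so each day gets its own logit-scale
estimate with a Wald interval, back-transformed to probabilities. Days
on which the response never (or always) occurred have no finite
estimate and are dropped with a warning.

## Synthetic-data generator

The generator's defaults emulate the study system's published regime;
they are conditions, not free parameters. Where the emulated system
states a value it is used directly; the remaining choices are noted
below with their rationale.

- **Layout**: 16×16 grid, 39 m spacing, coordinate jitter SD 5 m. The
  jitter SD was chosen so the mean 4-nearest-neighbor distance stays
  within a few meters of 39 m (the regime "39 m ± 7 SD").
- **Occupancy** 0.55 per box per season → ~140 pairs per season, the
  middle of the emulated range; with the tessellation this yields on
  average ~0.9 unoccupied boxes per territory, matching the reported
  regime.
- **Phenology**: nest start ~ N(1 April, 5 d); nest-to-first-egg lag
  ~ N(14, 3) d (min 5); clutch 7 + Poisson(3.5) (~10.5 eggs); one egg
  per day; incubation 14 d from clutch completion; nestling period
  20 d. 10% of attempts fail; 10% of new breeders are tagged after
  nest building (and are excluded by the pipeline, as in the emulated
  protocol).
- **Foray hazard** (per breeder-day, logit scale): sex baseline +
  linear seasonal trend (−0.015/d) + female decline of −0.25/d starting
  3 days before the first egg + male drop of −2.5 on the hatch day,
  plus a per-individual normal intercept. The baselines (−2.30 male,
  −3.25 female) and individual SD (2.7) were *jointly calibrated by
  numeric search against three published descriptive statistics* — a
  visit on ~11% of breeder-days, ~62% of breeders ever visiting, males
  > 3× females — before any recovery test was run. The large
  individual SD is forced by that joint regime: a homogeneous
  population cannot have an 11% day rate while 38% of breeders never
  visit. Individual intercepts persist across seasons (consistent
  individual differences).
- **Destination choice**: weight ∝ exp(−d/30 m) × 0.35 if the box is
  occupied × 2.5 for male visitors when the host female is 0–5 days
  into laying. The occupied-box weight is calibrated to the reported
  ~35% share of visits targeting occupied boxes; the fertility window
  produces the received-visit peak in early laying. Visits per foray
  day and readings per visit are geometric (p = 0.5, so half of
  box-days have a single visit, as reported); within-visit reading gaps
  are exponential (40 s), far inside the merge window.
- **Diel timing**: mixture of a mid-morning normal bump (sunrise +
  3.5 h, SD 1.5 h, weight 0.45), a pre-sunset bump (sunset − 0.75 h, SD
  0.75 h, weight 0.25) and a daylight-uniform floor; sunrise/sunset from
  a sinusoidal day-length approximation for ~48° N. This reproduces the
  "large daylight majority with small pre-dawn and post-dusk tails"
  pattern without modelling twilight explicitly.
- **Extrapair paternity**: each (brood, candidate-sire) dyad within two
  neighborhood orders succeeds independently with
  logit = c + 0.65·(male visited the female's territory) + 0.65·(female
  visited the male's) − 1.5·order; winning sires are then allocated one
  or a few offspring of the clutch, the rest staying within-pair. The
  dyad-level "shared extrapair young" outcome therefore follows exactly
  the logistic law the dyadic analyses fit — an earlier per-offspring
  "claims" mechanism was replaced because OR-ing claims over a ~10-egg
  clutch attenuated the dyad-level estimand to roughly half the
  configured effect. The intercept c is auto-calibrated by bisection on
  the *analytic* expected share of broods with ≥ 1 extrapair offspring
  (target 0.5). Effect sizes sit near the dyadic log-odds scale of the
  emulated analyses. Note the focal-sex analyses each omit the other
  direction's visit covariate, so their estimates are mildly attenuated
  relative to 0.65; recovery tests therefore check sign and CI behavior,
  not exact equality.
- **Dispersal**: survivors return with probability 0.5; movers (35% of
  returning females, 8% of males — chosen to land near the emulated
  female ≈ 18% / male ≈ 4% *dispersal* rates after the conjunctive
  > 70 m + outside-territory rule is applied) choose a new box with an
  exponential distance kernel (60 m), **independently of visit
  history**. This independence is the generator's built-in null: the
  dispersal models are validated by their ability to cover zero.

What the generator does **not** emulate: detection error and antenna
outages (every foray at a box is read), replacement clutches, partial
brood sampling in parentage, immigration/emigration between seasons
beyond simple replacement, and within-day dependence of foray timing on
breeding stage. Passing recovery tests therefore demonstrates that the
pipeline correctly recovers the structure the generator encodes — not
that field data meet these idealizations.

## Validation sizes and runtimes

The acceptance-style suite runs at sizes chosen to finish in minutes on
one CPU while keeping Monte-Carlo error well inside the asserted bands:
50 random layouts (9–60 territories) with 10⁴ nearest-site probes each;
1,000 random reading streams against a brute-force partition; 30 full
pipeline replicates at the default scale (~140 pairs, one season) for
sign recovery; 200 direct replicates (300 individuals × 10 dyads,
β = 0.7, σ² = 0.5) for Wald-CI coverage; 200 re-drawn dispersal
outcomes for null fidelity; 12 seeds for the extrapair-incidence
calibration band. The methods above are identical at any size; only the
replicate counts are implementation choices.

## Known limitations

- The Laplace approximation is mildly biased toward zero for binary
  data with large random-effect variances (a few percent here); this is
  a property of the approximation, shared with `glmer` defaults, not of
  the implementation.
- Neighborhood order depends on the tessellation at the study-area
  boundary; a different boundary choice can change adjacency of edge
  territories. How the emulated study bounded edge territories is not
  documented; the buffered-hull default is a reasonable stand-in, and
  the geometry oracles test the implementation, not the boundary
  convention.
- Dyadic tables treat dyads as independent given the focal random
  intercept; shared-partner dependence (the same male appearing in many
  females' candidate sets) is ignored, as in the emulated analyses.
- With single-digit disperser counts the dispersal models are at the
  edge of identifiability by construction; the separation flag, not the
  point estimate, is the informative output there.
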