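# Methods

## Scope and data flow

The package models a three-stage quality-control workflow for a
multi-compound herbal extract: (1) score each extraction run on many
quality indices at once via overall desirability (OD); (2) model the
OD response over a three-factor Box–Behnken design (BBD) with a
second-order polynomial and locate the constrained optimum; (3)
calibrate, validate and apply a UHPLC assay that converts peak areas
to mg/g contents per batch. The published worked example ships as
packaged CSVs (the 17-run design with OD responses, the factor level
schedule, the per-analyte calibration properties, and the 24-batch
content table); everything without published raw data is exercised on
synthetic data with known ground truth.

## Desirability aggregation

Indices are normalized per experiment table with the linear min–max
(Hassan) transform, mirrored for smaller-is-better indices, and
aggregated by the unweighted geometric mean. Two deliberate choices:

* **Exact zeros.** OD is exactly 0 whenever any dᵢ = 0 — no epsilon
  floor. The published design contains two such runs (OD printed as
  0.0000), and an epsilon would leak into the surface fit.
* **Per-table bounds.** Y_min/Y_max are the extremes of the table
  passed in, not global constants, so desirabilities are comparable
  only within one experiment. Fixed bounds can be supplied instead;
  values outside them are clamped to [0, 1] with a warning.

Derringer–Suich two-sided/target desirabilities and per-index weights
are out of scope: the aggregation here is the plain geometric mean.

## Design generation and coding

Only the k = 3 BBD is generated (12 edge midpoints + n_center centre
replicates); other k are rejected rather than approximated. Runs are
emitted in a fixed canonical order (factor pairs (1,2), (1,3), (2,3);
signs (−,−), (+,−), (−,+), (+,+); centres last). Execution order in
the lab was randomized, but every statistic computed here is
order-invariant, and a canonical order makes tests and diffs exact.
Coded levels are stored as integers −1/0/+1 so column orthogonality
and replicate identification are exact, not approximate. Coding is
xᵢ = (Xᵢ − centre)/half-range; the inverse round-trips to 1e−12.
A factor whose centre is not the midpoint of (low, high) is accepted
with a warning — the coding is then asymmetric but well-defined.

## Surface fitting and ANOVA

The 10-term quadratic is fitted by `numpy.linalg.lstsq` on the coded
model matrix; an independent OLS implementation (statsmodels) serves
as a cross-check in the tests, never as the fitting path. The ANOVA
mirrors Design-Expert output, which is what practitioners compare
against:

* **Partial (drop-one) SS per term**: SSE(model without the term) −
  SSE(full model), each F-tested against the full-model residual mean
  square. On the orthogonal coded columns this reduces to β²·8 for
  linear terms and β²·4 for interactions (asserted in tests); the
  quadratic columns are not orthogonal to the intercept, so per-term
  SS do not sum to the model SS — a documented non-identity. The
  identity that always holds is SST = SS_model + SSE.
* **Lack of fit**: replicate groups are found by exact equality of
  coded rows; pure-error SS is the within-group SS, lack-of-fit is
  the remainder, F-tested against the pure-error mean square. For the
  17-run/5-centre design the df split is 9/7/3/4. With no replicated
  rows the decomposition is skipped with a warning, never fabricated;
  with noiseless replicates (pure-error MS = 0) the lack-of-fit F is
  reported as undefined.
* p-values come from the F survival function (`scipy.stats.f.sf`);
  formatted reports round SS to 4 decimals and F to 2, matching the
  usual report precision.

## Constrained optimization

Bounds default to the coded design cube. The solver is multi-start
bounded L-BFGS-B from all 27 lattice points of {−1,0,1}³ plus, when
the quadratic form is negative definite, the closed-form stationary
point −½A⁻¹b, plus a deterministic shrinking-grid coordinate
refinement as a derivative-free fallback. Near-ties (within 1e−8) are
broken by the coded-lexicographically smallest point, so results are
bit-reproducible. Tolerances: gradient 1e−10, position 1e−8 coded
units. Boundary flags matter scientifically here: the worked
example's optimum sits on the +1 face of the liquid-to-solid ratio,
i.e. the data cannot exclude a better ratio beyond the design range —
the flag is how the package surfaces that caveat. `round_to_practice`
snaps actual levels to operator increments (round-half-away-from-zero
on the quotient) and re-predicts; a snap that leaves the cube is an
error rather than a silent extrapolation.

## Method validation and quantification

Calibration is unweighted OLS (1/x weighting is available but off by
default, since the reference workflow states none). LOD/LOQ
multipliers are explicit parameters with ICH defaults (3.3, 10): the
published limits show a ≈2:1 LOQ:LOD ratio, i.e. a different
convention whose exact formula is not stated, so the package never
claims to regenerate them — tests exercise the configurable-multiplier
path on constructed data instead. RSD uses the n−1 standard
deviation. Contents follow C·V·dilution/mass/1000 (µg/mL → mg/g);
concentrations outside the calibration range are flagged but kept,
because the smallest analytes sit near the range bottom and dropping
them would corrupt batch totals. Batch ids follow the
`<site>/<Month>` convention; any other format must be mapped
explicitly.

## Synthetic data

The generators emulate the study's data-producing steps with known
truth:

* **BBD responses**: Y = quadratic(β, x) + N(0, σ), seeded. The
  default truth in the analysis drivers is the surface fitted to the
  published design, with σ = 0.02 — the scale of the published
  pure-error mean square (≈0.0009 ⇒ replicate sd ≈0.03).
* **Calibration standards**: area = slope·C + intercept + N(0, σ),
  six geometrically spaced levels across each analyte's published
  range; σ at 0.5 % of the top-standard signal puts refit R² in the
  high 0.999s, matching a well-behaved DAD assay.
* **Chromatograms**: sums of pure Gaussian peaks on a uniform grid
  (default step 0.01 min) under a six-segment detector-wavelength
  schedule over a 28-min run; a peak's effective height is rescaled
  by its per-wavelength response factor exactly at segment
  boundaries. Peak tailing, the full time × wavelength DAD matrix and
  baseline drift are deliberately not modelled — the simulator exists
  to exercise segment-switch and integration logic, not to imitate a
  real detector, so passing tests say nothing about peak-shape
  robustness on real instruments. Integration is baseline-subtracted
  trapezoidal quadrature with a linear baseline between window
  endpoints; its error shrinks with the grid step (a convergence
  test covers three steps).

Per-compound UV response factors at each segment wavelength are not
published; the synthetic factors are declared inputs and are never
claimed to match the real analytes. All generators take mandatory
seeds in the library API; the CLI defaults to seed 20220710.

## Problem sizes and determinism

Everything printed by the analysis drivers and the acceptance script
is recomputed at run time on desk-scale inputs: the 17-run design,
200-replicate Monte-Carlo recovery (50 replicates for the optimum
RMSE), 6-point calibrations for 11 analytes, and 0.001-min grids only
inside integration tests. The whole suite runs in well under a
minute. The surface fit, ANOVA and optimizer are fully deterministic;
simulation-based checks fix their seeds.

## Known limitations

* Only three-factor BBDs are generated; the fitting/ANOVA code is
  written for general k but is exercised only at k = 3.
* The desirability module operates on whatever index table it is
  given; whether indices are raw contents or per-gram yields is the
  caller's modelling decision.
* The published validation figures (R², RSDs, recoveries) and batch
  contents rest on unpublished raw replicates; the packaged copies of
  those tables support format ingestion and consistency checks, not
  regeneration.
* A boundary optimum (as in the worked example's liquid-to-solid
  ratio) is flagged, not resolved: deciding whether the response
  keeps rising beyond the design range needs new experiments.
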