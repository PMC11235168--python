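# Methods

## Quantities and notation

All isotope values are δ²H in ‰ on the VSMOW scale. Values at or below
−1000‰ are rejected as non-physical. ε values are apparent (net)
fractionation factors expressed as plain delta differences; the
ratio-domain alternative 1000·((1000+δ_A)/(1000+δ_B) − 1) is provided as a
separate function (`epsilon_ratio`) and is never silently substituted,
because the difference convention is what the summary statistics in this
field are reported in.

## Equilibration reduction

Carbohydrate O-bound hydrogen exchanges with ambient water; the dual
water-vapor equilibration method isolates the carbon-bound
(nonexchangeable) signal. The reduction implements the two printed-form
relations exactly in delta notation, including the 1000·(α−1) term:

- exchanged fraction x_e = (δe1 − δe2) / (α_e−w · (δw1 − δw2)),
- δ²H_ne = (δe − x_e·α_e−w·δw − 1000·x_e·(α_e−w − 1)) / (1 − x_e).

Defaults: equilibration waters −160 and −428‰, α_e−w = 1.082 (the
cellulose value, applied to all carbohydrate classes and exposed per
measurement). Substituting the definition of x_e into the δ²H_ne relation
shows the two pairs give *identical* results in exact arithmetic; the
per-record `pair_residual` is therefore a numerical/data-integrity
diagnostic, flagged (`PAIR_INCONSISTENT`) above 1e-6‰. x_e outside [0, 1]
is reported with `X_E_OUT_OF_RANGE` and never clamped — clamping would hide
exactly the QC problems the dual measurement exists to catch.

Correction order follows the measurement workflow: additive offset
correction of the raw equilibrated deltas against exchange-free standards
(IAEA-CH-7 polyethylene foil), then the x_e/δ²H_ne reduction using pair 1,
then an affine VSMOW calibration (exact two-point mapping, least squares
when more than two exchangeable standards are supplied). The in-house
standard values are laboratory-specific and must be user-supplied; the
batch runs without them (identity calibration). An optional amount
correction (bias linear in 1/amount, fitted on exchange-free standards
carrying amounts) is available but off by default, since no functional form
is canonical. A record that fails (e.g. x_e = 1 exactly, a singular, fully
exchanged case) is collected as a failure without aborting the batch.

## Fractionation factors

ε_a = δ²H_compound − δ²H_leaf water is evaluated for leaf sugars, starch,
cellulose, and the abundance-weighted n-alkane mean; ε_h = δ²H_A − δ²H_B for
the contrasts cellulose−sugars, cellulose−starch, starch−sugars within
leaves, within roots, and between roots and leaves (root compound minus
leaf compound). Samples pair by (treatment, replicate); missing compounds
yield absent rows rather than errors, since unbalanced replication (down to
n = 3 for cellulose and alkanes under NH₄⁺-dominated fertilization) is part
of the data structure. Tissue offsets average per-treatment means with
equal treatment weight — replicates are distinct plants, but treatment-level
summaries are the reporting unit.

The weighted alkane mean renormalizes abundances to sum exactly to one and
accepts raw sums in [0.98, 1.02]; chains absent from a sample are dropped
with renormalization over the remainder (equal weights when no abundances
are given, as the synthetic data carry none).

## The two-pool cellulose model

δ²H_cellulose = (1−f)·(δ²H_leaf water + ε_a*) + f·(δ²H_source water + ε_h*),
with defaults ε_a* = −171‰, ε_h* = +158‰, f = 0.36. The model is affine in
every argument, so the single-parameter inversions for f (given ε_h*) and
for ε_h* (given f) are closed-form and exact; both are provided because the
data alone cannot disentangle which parameter varies. `eps_a_used` may be
the constant ε_a* or a measured dynamic ε_a of sugars or starch
(`eps_a_mode`), which is the comparison of interest when assimilate-level
fractionation varies with treatment. Inverted f outside [0, 1] is flagged,
not clamped: negative f is a meaningful diagnostic (the observation falls
below the pure leaf-water pool). Per-treatment inversion uses treatment-mean
inputs by default, with a per-replicate mode.

Source water is root water by default; soil water is available as a
sensitivity mode because cryogenic extraction can bias root-water δ²H.
Because the model is affine, the substitution shifts every prediction by
exactly f·(δ_soil − δ_root); with f = 0.36 and the observed 6.7‰ root
depletion that is +2.41‰. The package reports the signed shift and leaves
interpretation to the user.

## Hydrogen budgets

Glucose has 7 carbon-bound H, stored as integer source counts 1:3:3
(NADPH:water:precursor), reproducing 14/43/43% under
round-half-away-from-zero to whole percent. An unbranched saturated
n-alkane of n carbons has 2n+2 carbon-bound H (60 for C29); its source
split 47/24/29% is a literature accounting constant stored as percentages
(47% of 60 is not an integer atom count) and applied to C27–C33 alike — the
underlying biosynthetic bookkeeping is not re-derived here. `mix_delta`
is plain linear mass balance Σ fraction·(δ_source + ε_source), intended for
scenario exploration; it assumes no H exchange between pools after
assembly.

## Synthetic experiments

The generator defines the study conditions under which the pipeline is
exercised; its defaults are the treatment-level summaries of the tobacco
experiments it emulates and are not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| treatments | 100, 90, 75, 50, 25, 10, 0 | NO₃⁻ percentage of the N supply |
| n_replicates | 5 | plants per treatment |
| irrigation_water | −79.3‰ | source/root water baseline |
| vapor_water | −140.0‰ | chamber vapor (context; not consumed downstream) |
| leaf_root_water_offset | +29.6‰ | evaporative leaf-water enrichment |
| soil_minus_root_water | +6.7‰ | extraction-related root-water depletion |
| root − leaf offsets | +17.3 / +104.5 / +12.3‰ | sugars / starch / cellulose |
| base ε_a (leaf) | −161.8 / −203.8 / −73.5‰ | sugars / starch / cellulose at the NO₃⁻ end |
| alkane ε_a | −128.8‰ | flat across treatments |
| amplitudes | 128.8 / 77.6 / 35.4‰ | max leaf δ²H range along the gradient |
| breakpoint | 25 | NO₃⁻ % where the response turns |
| noise_sd | 3‰ | midpoint of the 2–4‰ measurement precision |
| pgm offsets | +152.7 / +75.0 / +38.7‰ | starch / sugars / cellulose; alkanes 0 |

The treatment response is piecewise linear in the NO₃⁻ fraction — flat for
NO₃⁻ ≥ 25%, rising linearly to the configured amplitude at 0% — the
simplest shape consistent with a flat-then-rising response with a turning
point at 25/75; no functional form is canonical. Noise is independent
Gaussian per record, conflating between-plant and measurement variance into
one term because the two are not separately quantified; there is no
plant-level random intercept by default. Missingness deterministically
truncates cellulose and alkane records to 3 replicates at the 10/90 and
0/100 treatments. Water δ²H is held flat along the gradient (its real
variation, ≤ 12.5‰, is small against the assimilate effects and is not a
target of any downstream check).

What passing tests show — and do not show: at zero noise every configured
effect size is recovered exactly through the analysis stages, proving the
algebra and the plumbing, and at realistic noise the Monte-Carlo recovery
checks bound estimator bias. None of this validates the biological model
against real plants; the generator has no covariance between compounds
beyond shared leaf water, no day/night dynamics, and no trait correlations.

## Numerical choices

- Exact-identity assertions (pair consistency, model inversions, zero-noise
  round trips) use 1e-9‰, pure floating-point headroom with no measurement
  meaning.
- VSMOW calibration refuses standards with identical measured values
  (degenerate affine fit); the exchange reduction refuses identical
  equilibration waters and x_e = 1 with explicit errors rather than
  division blow-ups.
- Percent rounding is half-away-from-zero, matching how the published
  percentages were formed.
- Seeds: every stochastic path takes a single integer seed through
  `numpy.random.default_rng`; identical seed + config ⇒ byte-identical
  outputs (asserted in the pipeline tests).

## Problem sizes

The test suite runs the pair-consistency identity over 10,000 randomized
measurements, noise-level recovery at n = 200 equilibrations and n = 100
model inversions, and the full synthetic gradient at its native size
(7 treatments × 5 replicates, ~430 records); the whole suite completes in a
few seconds.

## Known limitations

- The pipeline treats the leaf-water record as given; it does not model
  evaporative enrichment (no Craig–Gordon stage).
- ANOVA/post-hoc statistics, PCA, and trait regressions are out of scope;
  the outputs are tidy CSVs ready for any statistics environment.
- The alkane H-source percentages are C29 constants applied to all chains.
- The in-house VSMOW standard values are laboratory property and must be
  supplied by the user for absolute-scale work.
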