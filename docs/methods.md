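# Methods

## Metabolic model and design arithmetic

Individual metabolic rate is the power-law reduction `I = a·M^b` with
defaults `a = 0.69` mJ day⁻¹ (mg AFDW)⁻ᵇ and `b = 0.79`, valid for
surficial motile freshwater gastropods near 18 °C; organism energy density
defaults to 21.5 J mg⁻¹ AFDW. The full multi-predictor respiration model
from which this reduction derives is deliberately not implemented: the
power law with configurable `(a, b)` reproduces every downstream design
number, and the coefficients are exposed for other taxa or temperatures.
One consequence is accepted rather than chased: at `M = 12.88`,
`I = 5.20` mJ day⁻¹, while the conventional rounded value for
*G. truncatula* is 5.25 — a rounding of `(a, b)` upstream of this package.

Cohort energetics are exact sums: biomass `n·M`, overall rate `n·I(M)`,
per-biomass demand `I(M)/M ∝ M^(b−1)`. Equivalent cohort sizes are
`round(target / per-individual)` with the raw ratio always reported,
because real cohorts (7 and 145 at biomass equivalence) are not exact
quotients. Using *unrounded* individual rates, the energy-equivalent
counts of the two smaller species against four *G. truncatula* come out as
`20.786/3.485 = 5.96 → 6` and `20.786/0.3146 = 66.07 → 66`; rounding the
rates to 2 d.p. first would give a different count (67.7 → 68) for the
smallest species, which is why the unrounded path is the implemented one.

Rate CIs propagate the size CI only, by the first-order delta method
`ΔI = a·b·M^(b−1)·ΔM`. Parameter uncertainty of `(a, b)` is excluded; the
resulting half-widths are therefore a lower bound on the published-style
CIs, which include model error.

## Tracer accounting

`(raw − blank)/efficiency`, clamped at zero with a warning (blanks can
exceed near-background samples), then decay correction
`×2^(Δt/half-life)` to a reference instant, then curie conversion at
1 DPM = 4.556×10⁻¹³ Ci. The ³²P half-life defaults to 14.268 days and the
reference instant to the trial start; both are configurable because
neither is dictated by the data format. Whether start-control disks should
renormalise series-level charge is left as an explicit switch the caller
can apply; the default uses final controls only, as the exploitation
denominator.

## Descriptors

* **GUT**: arithmetic mean of `departure − entry` over leavers only;
  foragers present at the 96 h horizon are censored and excluded (the
  study's rule), not survival-modelled. With no leavers GUT is undefined
  (NaN) and carries the leaver/censored counts.
* **Net accumulation rate**: final body charge over time on patch.
  Censored foragers use the full horizon as denominator — they
  demonstrably fed throughout the trial.
* **GUD**: mean residual charge of the grazed disks.
* **Exploitation**: `1 − grazed/control` against the same series' final
  controls. The complement (exploited share), not the raw residual ratio,
  is the primary value because that is the direction in which the results
  are interpreted; both numbers are emitted, and negative exploitation is
  flagged rather than suppressed.

Descriptor CIs are t-based. Per-treatment summaries average the (by
default four) independent series values and attach a t CI across series.

Departure times are discretised to the observation grid: checks every
30 min while the clock is in the 06:00–18:00 daytime window, plus one
check at the end of each night block; a departure is recorded at the first
check at or after the true instant, and a true time past the last check is
censored. The day window and trial start clock (default 06:00) are
configurable.

## Energy-equivalence interpolation

Within each series, each descriptor is interpolated linearly between the
two observed abundances bracketing the energy-equivalent count
(piecewise-linear with exact passthrough at observed abundances);
out-of-range targets extrapolate from the nearest segment with a warning.
A global least-squares line is available as `mode="global_linear"`, but
piecewise is the default because it is the only variant that reproduces
observed endpoints exactly. Modelled rows are flagged and excluded from
the within-species abundance fits; the cross-species *energy* class fit
uses them by construction — that class exists only through interpolation.
Series GUT points with no leavers are dropped from the interpolation with
a warning; if fewer than two abundances remain the series is skipped.

## Scaling fits

Log-log OLS with natural logs throughout (the base only shifts
intercepts). Observations are series-level means per treatment, not
per-forager records — four independent replicate values per treatment is
the replication structure, and per-forager fits would understate the
between-series variance. Intercepts are back-transformed (`a = e^α`); the
intercept CI half-width is the half-range of the back-transformed bounds.
Fractions are fitted as a binomial-family GLM with logit link on
`ln(x)`; boundary fractions are nudged into (0,1) by a configurable
ε = 10⁻⁶. McFadden's pseudo-R² is `1 − lnL_fit/lnL_null` with the
Bernoulli-form likelihood `Σ[y ln μ + (1−y) ln(1−μ)]` — fixed to this
(binomial) definition and cross-checked in the tests against a direct
numerical MLE. No multiple-testing correction is applied; descriptor
tests are reported raw. The residual-charge ANOVA groups disks by grazed
treatment plus the pooled final controls (8 groups, so 7 between-group
degrees of freedom under the default design).

## Synthetic study generator

The generator emulates the study conditions: 3 species at mean sizes
12.88 / 7.77 / 0.37 mg AFDW (individual sizes lognormal, CV 0.15), the 7
observed treatments (4 G. truncatula; 4 and 7 B. tentaculata; 4, 12, 79,
145 E. ventrosa), 4 series, 16 disks per patch at a nominal 31.2 nCi
initial charge (series means normal with SD 2 nCi, per-disk charges
lognormal with CV 0.10), 96 h horizon, 70% assimilation efficiency, and
the day/night observation schedule above.

Dynamics are discrete-time (Δt = 0.1 h). Intake per forager is
`c·M^γ·(R/R₀)` nCi h⁻¹ with defaults `c = 0.30` and `γ = 0.75` — a linear
functional response in the current mean disk charge `R`, chosen over a
Holling type-II form (available behind a switch) because it makes the
tracer-conservation identity exact and the depletion dynamics analytically
transparent. Ingested charge leaves disks in proportion to their current
charge; the assimilated fraction accrues to the body, so every trial
satisfies `initial disk charge = residual + body/efficiency` to rounding
error. A forager quits when intake falls below `q·I(M)·exp(s·ε)` —
a quitting-harvest-rate threshold proportional to its metabolic rate
(`q = 0.35` nCi h⁻¹ per mJ day⁻¹) with fixed per-forager logistic
heterogeneity (`s = 0.10`); below threshold, departure is a hazard of
1 h⁻¹, reduced tenfold at night since these grazers barely move in the
dark. `q = 0` recovers the no-departure limit. `c` and `q` were set so
that the largest species gives up within roughly a day while the smallest
cohorts at low abundance mostly never leave, and `s` so that leaver GUTs
spread over several hours — magnitudes chosen as realistic for the system,
as tuning, not inference; the *directions* (GUT falling with size and
abundance, GUD falling and exploitation rising with abundance) emerge from
the mechanism, and those are what the tests assert.

The generator also emits synthetic raw scintillation counts by pushing the
true charges backwards through a non-trivial calibration (efficiency 0.9,
blank 25 DPM, measurement 5 days after trial start), so the tracer stage
is exercised, and a ground-truth JSON (seed, generating parameters, true
departure instants) for recovery tests.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: spatial structure within the patch, travel
time between patches, interspecific competition, feeding-mode switches,
diel activity beyond the night hazard factor, disk conditioning trends
over series, and measurement error beyond the calibration chain.

## Parameter recovery

The recovery check fits series-mean net accumulation rate against mean
body size across species *at energy equivalence* (12 points: 3 species ×
4 series). At matched overall demand the patch is depleted at the same
rate for every species, so the realised time-averaged intake remains
proportional to `c·M^γ` and the log-log slope estimates γ without the
depletion bias that flattens the numeric-equivalence contrast (where the
large-species cohort strips its patch faster). Across seeds the recovered
slope is unbiased to within ~0.01 with a seed-to-seed SD of ~0.015, and
its 95% CI covers the generating γ = 0.75.

## Numerical choices and degenerate inputs

Time step 0.1 h (fine enough that threshold crossings resolve within the
30-min observation grid); departures land exactly on grid times.
Sub-blank counts clamp to zero; empty cohorts yield zero energetics with
a degeneracy flag; all-censored trials yield NaN GUT with counts; zero
descriptor variance yields zero CI half-widths; Pearson r on
zero-variance input is NaN with a degeneracy flag. The default study
sizes (4 series, ~1020 foragers, 512 disks) run the full pipeline in a
couple of seconds, which is why the test suite can afford full-study
fixtures.
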