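# Methods

## The estimand and the accounting model

The quantity estimated is the Average Population Present (APP): the
average nightly number of people physically in a region over a month,
i.e. person-nights divided by the number of nights *n(t)* in the month.
APP aggregates cleanly over space and time (unlike peak population or
visitor counts), at the cost of damping within-month maxima.

The account for region *s*, month *t* is

    unscaled(t,s) = ERP(t,s) + visitors_dom(t,s) + visitors_int(t,s)
                    − absent_dom(t,s) − absent_int(t,s)

followed by proportional benchmarking to a national monthly control
series. The four flow components are annual national person-night
totals distributed over (region, month) cells by estimated share
surfaces and divided by *n(t)*. The annual totals are interpreted as
person-nights throughout (not trip or visitor head counts): only then
does share-of-annual-nights ÷ nights-in-month have units of average
nightly persons, matching the APP definition.

## Share models

Two Poisson GLMs with log link are fitted to count panels with one
observation per (region, month) cell and a constant offset log(ΣY):

* destination model: intercept + month + month×climate +
  month×remoteness, fitted to short-stay accommodation visitor nights;
  its share surface λ̂ distributes both the domestic and the
  international visitor totals;
* origin model: intercept + month + month×remoteness, fitted to
  resident-departure nights; its surface η̂ distributes both
  absent-resident totals.

The contract is stated on the design **column space**, not a coding:
"interaction without main effect" notation is coding-ambiguous, but the
fitted cell means — the only quantity used downstream — depend only on
the column space (verified by a coding-invariance test). The
implementation uses treatment coding with the first observed level of
each factor as reference; rank deficiency (e.g. climate perfectly
confounded with remoteness across regions) is detected by pivoted QR
and reported by naming the aliased columns.

Because the model has an intercept and the canonical link, the score
equations force Σ fitted means = Σ counts, so fitted shares sum to one
over the fitting cells without any explicit normalisation; prediction
over a different cell set renormalises and records the multiplier.
Fitting is IRLS (statsmodels GLM), capped at 100 iterations with a 1e-8
deviance-change tolerance; non-convergence is flagged and blocks
prediction unless explicitly overridden. Fitted shares below 1e-12 are
clamped to zero and the surface renormalised; no pseudo-counts are
added by default, but an optional L2 ridge (`ridge` run option) is
available for degenerate user data. One observation per (region, month)
cell rather than per class×month aggregate keeps shares normalised at
region level, which person-night conservation of the components
requires; when every region in a class has complete data the two
choices give identical fits (factor-saturated equivalence).

## Constraint stage

The monthly gap Δ(t) = national(t) − Σₛ unscaled(t,s) is allocated
proportionally to each region's share of the month's unscaled total and
added on. The proportion is computed per (t, s) — it necessarily varies
by month even though it is sometimes written as a function of *s*
alone. This guarantees Σₛ APP(t,s) = national(t) exactly, is idempotent,
and allocates adjustments in exact ratio to unscaled size. Negative
unscaled cells (more residents absent than ERP plus visitors) are
retained with a warning rather than clamped, because clamping would
silently break the conservation identity; region exclusion (for
degenerate inputs such as near-zero ERP) is an explicit configuration
list applied before any fitting.

## Metrics

APP/ERP ratios require strictly positive ERP (violating regions must be
excluded). Peak-season classification takes the argmax month of each
region's 12-month ratio series (earliest month on exact ties) and maps
it through Southern-Hemisphere half-years — summer = {Nov…Apr}, winter =
{May…Oct} — giving a binary, exhaustive classification; the month sets
are configurable. Summary percentages truncate toward zero (253/335 →
75%), the convention used when such counts are reported. Candidate-panel
correlations are Pearson by default, Spearman by option, over flattened
aligned (region, month) cells.

## Synthetic data generator

The generator emulates the study's data environment with known ground
truth:

* regions drawn from a configurable (climate, remoteness) mix; default
  20 regions, uniform over 3 climate zones × 4 remoteness classes —
  enough cells to identify every interaction while keeping tests fast;
* ground-truth share surfaces that are log-linear in exactly the column
  space the models fit (cosine seasonal effects, amplitude ≤ ~0.5 on the
  log scale, with remote classes phase-shifted toward winter peaks, as
  in dry-season tourism regions);
* independent Poisson counts per cell with mean share × total_nights
  (default 10⁶ nights per panel). Independent Poisson rather than
  multinomial matches the fitting likelihood; the realised total then
  differs from the configured one by sampling noise, the realistic case;
* annual totals defaulting to 30M (domestic visitor), 10M
  (international visitor), 30M (domestic origin) and 12M (international
  origin) person-nights against an ERP base of 50,000 persons per
  region (lognormal spread, σ = 0.4) — magnitudes chosen so visitor and
  absence flows move regional populations by a few per cent, the
  realistic regime;
* ERP constant within the year per region: no sub-annual resident
  dynamics are emulated because none are specified for the real series;
* a national control series equal to the monthly sum of the true
  unscaled account times (1 + `national_perturbation`); with the default
  0 the constraint stage is a no-op on the truth, and a nonzero value
  injects a known relative gap to exercise it.

Everything derives from a single mandatory seed (child streams via
`SeedSequence`); identical configurations produce byte-identical CSVs.

What passing tests on this world do **not** show about real data: the
generator has no spatial autocorrelation, no overdispersion (a
negative-binomial flag is a possible extension, off by default), no
within-month dynamics, no selection bias in the accommodation panel,
and its share surfaces satisfy the model's own functional form exactly —
so recovery results certify the estimator, not the adequacy of the
model for any particular real panel.

## Numerical choices and test problem sizes

* Share normalisation tolerances: 1e-9 on fitted surfaces (score
  equation), 1e-6 on surfaces entering the component stage.
* Monthly conservation asserted at 1e-6 relative; achieved at float
  rounding (~1e-16).
* `majority_class` breaks ties lexicographically, for determinism.
* Tests and the acceptance script use 20-region × 12-month scenarios
  with 10⁶-night panels (seconds per fit), a 400-replicate Monte-Carlo
  check of the Poisson generator, and a 100-table sweep of the
  constraint properties; these sizes give stable results while keeping
  the full suite under ten seconds.

## Known limitations

* No uncertainty quantification: point estimates only; a hierarchical
  Bayesian treatment is the natural extension.
* One national margin: no iterative proportional fitting to multiple
  margins.
* The same destination share surface distributes domestic and
  international visitor totals; a separate international model would
  need its own high-resolution panel.
* Monthly regional ERP is consumed as given; the package does not
  interpolate annually updated ERP.
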