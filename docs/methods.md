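# Methods

## Model

`bluepolicy` classifies countries against policy objectives with a
crisp-set (binary-membership) rule model, a deliberately simple variant
of qualitative comparative analysis. The model has three layers.

**Conditions.** A condition is a threshold test on one national-average
indicator: direction (`greater`/`less`), cutoff in indicator units, and
a strictness flag for the boundary. Comparisons are strict by default
(`>` / `<`), matching the phrasing of the one theoretically anchored
cutoff shipped with the package — more than 10% of a population at risk
of inadequate vitamin B12 or omega-3 intake (summary exposure value
above 0.10). Crisp membership is three-valued: in, out, or missing when
the indicator is unrecorded. Missingness is explicit end to end — an
empty CSV cell or literal `NA`, never a numeric sentinel, because zero
is a meaningful value for every indicator in the schema.

**Solution formulae.** Each policy carries two monotone Boolean
formulae (AND/OR over condition ids; negation is rejected at parse
time), one per tier. Monotonicity is load-bearing, not cosmetic: it
guarantees that (a) crossing more thresholds can only raise a country's
tier, (b) one-at-a-time cutoff scans of greater-direction conditions
produce non-increasing combined-relevant counts, and (c) three-valued
evaluation is fully determined by the two extreme completions of the
missing slots.

**Evaluation and assignment.** Formulae are evaluated under strong
Kleene logic (OR true if any operand true; AND false if any operand
false; UNKNOWN only when a missing operand is decisive). The class per
(country, policy) is: highly relevant if the first-tier formula is
true; else relevant if the second-tier formula is true; less relevant
if both are false; missing data otherwise. Consequences worth noting:

* A satisfied OR arm rescues a country despite a missing co-variable —
  availability established through known-high imports does not become
  "missing data" because production is unrecorded.
* A false necessary condition dominates a missing one: a country with
  in-bounds low deficiency and unrecorded availability is *less
  relevant*, not missing data, because no completion of the missing
  value could make the formula true.
* The four classes partition the country set per policy; this is
  asserted on every run.

No Boolean minimization (e.g. Quine–McCluskey) is performed: the model
applies given formulae, it does not derive them from observed truth
tables.

## Default rule configuration

The shipped config (`src/bluepolicy/data/default_rules.yaml`) encodes
five policy tracks: vitamin B12 deficiency, omega-3 deficiency,
cardiovascular disease linked to red meat, ruminant-meat greenhouse-gas
footprints, and climate-safeguarding of blue-food dependence. Formula
shapes follow the stated conditions of each objective — deficiency AND
availability; meat intake AND disease burden AND availability; ruminant
intake AND availability; dependence (employment OR export OR nutrition
share) AND climate hazard — with availability always expressed as
production OR imports.

The main text of the underlying framework fixes only the 10%
nutrient-risk cutoff. The highly-relevant tier is expressed as the same
conjunction at stricter cutoffs (e.g. SEV > 0.25, selected at a natural
break of the synthetic preset's beta marginals); every cutoff other
than the 10% one is a placeholder in the same sense and is tagged
`calibrate-to-supplement` in the config. All cutoffs, directions,
strictness flags and formulae are user-editable YAML; a SHA-256 digest
of the canonicalized config is recorded in every output manifest so a
classification can always be traced to the exact rules that produced
it.

## Sensitivity analysis

The one-at-a-time scan re-runs the classification with a single
condition's cutoff replaced by each value of a trial grid, leaving all
other conditions and all formulae constant, and records the per-class
country counts at each point. The grid is the union of (a) `n_points`
equally spaced values over the observed [min, max] of the indicator,
(b) every observed unique value, and (c) the configured baseline
cutoff. Part (b) guarantees every count transition is captured exactly
(counts can only change when the cutoff crosses an observed value);
part (c) guarantees the curve contains a point that reproduces the
unperturbed classification. The default `n_points` is 101 — smooth
curves at trivial cost, with exactness supplied by the observed-value
union rather than grid density. When two tiers share an indicator at
different cutoffs, each condition is scanned separately. Counts, not
country identities, are the primary output; per-country class
trajectories are available behind a flag for debugging. Variance-based
global sensitivity methods (Sobol, Morris) are out of scope — with
monotone Boolean rules, the OAT response is already exact and
interpretable.

## Overlap analysis

The two relevance tiers are combined (relevant := highly relevant or
relevant). For an ordered policy pair (row, col), countries classed
missing-data for either policy are excluded; the cell reports the count
of countries relevant for both and that count divided by the column
policy's relevant countries among the eligible set. Counts are
symmetric, proportions are not. A zero denominator is reported as
not-available rather than zero. Display percentages use round-half-up
to integers; raw proportions are always retained in the long-format
output so the rounding convention is auditable.

## Synthetic data

The generator emulates the *statistical structure* of an assembled
national indicator table, not geography: no attempt is made to match
real countries' values, and synthetic keys use a reserved `SYnnn`
format that cannot collide with real ISO3 codes.

Marginals are per-indicator families: beta for bounded shares, lognormal
for right-skewed intakes and disease burden, uniform for scores,
bernoulli for flags. Dependence is a Spearman rank-correlation matrix
imposed through a Gaussian copula: target rank correlations are mapped
to latent normal correlations via r = 2 sin(πρ/6), a latent
multivariate normal is drawn and pushed through the normal CDF and each
family's inverse CDF. Rank coupling (rather than raw Pearson) is used
so bounded and skewed marginals are preserved exactly. Missingness is
applied completely at random per indicator, after value generation —
no mechanism beyond MCAR is modelled, since MCAR suffices to exercise
the missing-data pathway; real multi-source national data will
certainly miss non-randomly, so test results involving missingness
speak to mechanics, not to bias behaviour on real data.

The study-shape preset draws ~190 countries with B12/omega-3 summary
exposure values rank-correlated at 0.7 (strong deficiency
co-occurrence), correlated red/ruminant meat intakes, and 5%
missingness per indicator. These values were fixed once as a realistic
emulation of the published setting and are not tuned.

`plant_classifications` inverts the classifier: given target class
counts for one policy, it enumerates representative indicator values in
every cutoff-delimited region (region midpoints, the cutoffs
themselves, and explicit missing), searches assignments exhaustively
until the classifier confirms each requested class, and replicates the
winning rows. The search is deterministic; the per-row class order is
shuffled from the seed. An unsatisfiable request (e.g. a required
region emptied by a cutoff at a variable's bound) raises a construction
error rather than returning an approximate table.

## Numerical and interface choices

* Grid/cutoff arithmetic is plain float64; grid de-duplication is exact
  (`np.unique`), which is safe because grid points come from observed
  values and linspace, not accumulated arithmetic.
* The latent copula correlation matrix is eigenvalue-clipped at 1e-12
  and renormalized only to absorb the tiny non-PSD perturbations the
  Spearman-to-Pearson map can introduce; genuinely inadmissible
  matrices are rejected.
* Output CSVs use fixed column order, LF endings and `%.6g` float
  formatting, so identical inputs give byte-identical files; the
  classification output is sorted by iso3, making results invariant to
  input row order.
* CLI exit codes separate data-validation failures (2, with a report
  file) from configuration failures (3); logs go to stderr, outputs to
  files only.

## Testing strategy and problem sizes

The three-valued evaluator is tested against an independent brute-force
oracle that enumerates *every* completion of the missing slots of
random monotone formulae (≤ 6 conditions, all 3^k membership
assignments), and separately against the two-extreme-completion
characterization. Classification is pinned by a ten-country fixture
whose classes are derived by hand in the test, and the planting round
trip (classify(plant(spec)) == spec) is exercised over 100 random
specs. Sensitivity and overlap invariants (conservation, monotonicity,
flatness, symmetry, missing-exclusion) are property-tested on random
tables. Routine suite runs use tables of 10–190 countries and scan
grids of 5–21 points; the copula and marginal-moment checks use one
draw of n = 10,000 with 3-standard-error tolerances. These sizes make
the full suite run in seconds while leaving every check exact rather
than approximate.

## Limitations

* The default non-nutrient cutoffs are calibrated to the synthetic
  preset, not to authoritative per-variable sources; conclusions from
  the default config apply to the synthetic setting only.
* Crisp sets discard within-threshold variation by design; countries
  just above and far above a cutoff are indistinguishable. The
  sensitivity scan is the provided instrument for assessing how much
  this matters for a given table.
* The tier distinction (highly relevant vs relevant) is expressed here
  as stricter-cutoff conjunctions; other formalizations (additional
  conditions per tier) are expressible in the YAML but not shipped.
* No data retrieval: the pipeline starts from a pre-assembled CSV.
  Assembling real FAO/WHO/ILOSTAT/World Bank inputs, and any fuzzy-set
  extension, are out of scope.
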