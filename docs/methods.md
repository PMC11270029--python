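# Methods

## Outcome construction: readability scoring

Speeches are scored from token counts:

- Flesch Reading Ease: `206.835 − 1.015·ASL − 84.6·ASW`
- Flesch-Kincaid grade: `0.39·ASL + 11.8·ASW − 15.59`
- RIX: long words (strictly more than 6 letters) per sentence

with ASL = words/sentences and ASW = syllables/words. The formulas are
evaluated exactly; everything upstream of them is a documented heuristic,
because real corpora delegate tokenization to text-analysis packages with
undocumented internals and reproducibility requires fixing the rules:

- **Sentences** end at `.`, `!`, `?` or `;` followed by whitespace and a
  capital letter, or at end of text; a fixed abbreviation list (`Dr.`,
  `Mr.`, `Mrs.`, `St.`, `No.`, `etc.`) suppresses splits.
- **Words** are alphabetic runs (internal apostrophes/hyphens kept);
  numerals count as one-syllable words.
- **Syllables** are maximal vowel groups (a e i o u y); a terminal silent
  `e` is subtracted only when it is preceded by a consonant and the word
  does not end in consonant+`le`; the count is floored at 1. The counter
  is English-oriented and pluggable (`tokenize_and_count(…,
  syllable_counter=…)`) so other-language heuristics can be swapped in;
  cross-language comparability of absolute scores is therefore
  approximate, though within-language regression results depend only on
  consistency.

Sample filters mirror the standard practice for plenary records: chair
speeches and speeches shorter than 25 words (strictly — a 25-word speech
is retained) are excluded, with a per-speech logged reason. Speeches that
tokenize to nothing are excluded as unscorable rather than scored zero,
to avoid polluting the outcome distribution.

## Weather features and exposure bins

Saturation vapor pressure uses the Magnus-type form
`E(T) = 6.11·10^(7.5T/(237.7+T))` (hPa, T in °C, domain T > −237.7);
relative humidity is `100·E(T_dew)/E(T_mean)`; wind speed is
`√(u² + v²)`. Units are fixed by contract (°C, hPa, m/s); precipitation
passes through untransformed. Inputs must arrive in these units.

Exposure is a partition of daily mean temperature into bins — the main
scheme `<0, 0–3, 3–6, 6–9, 9–12, 12–18 (comfort, reference), 18–21,
21–24, 24–27, >27 °C`, and a 9-bin variant for milder climates whose top
bin is `>24`. Shared endpoints in the labels force a boundary
convention: bins are uniformly lower-closed/upper-open `[lower, upper)`,
so 27.0 °C falls in `>27` and 12.0 °C in the comfort bin. Results for
observations exactly on a boundary depend on this convention.

Lag/lead exposures (`temp_bin_lag±k`) hold the bin of date+k in the same
city; a missing neighbour day yields a missing value that is dropped —
and counted — only at design assembly, never silently. Binary covariates
(e.g. a pollution flag for PM10 above the 50 µg/m³ guideline) use strict
exceedance.

## Fixed-effects estimation

The design regresses the outcome on non-reference bin dummies plus
controls, absorbing politician, month-by-city and day-of-week fixed
effects by alternating-projections demeaning (declared dimension order,
convergence when every column's largest absolute group mean falls below
1e−10 relative to the input scale, cap 10,000 sweeps). One dimension
demeans exactly in one sweep; crossed dimensions typically converge in
well under ten. Collinear columns after demeaning are pruned by pivoted
QR (relative threshold 1e−9 on the R diagonal) and reported. Singleton
fixed-effect groups are retained (they demean to zero) and counted.

Coefficients match dense dummy-variable least squares on the same rows
to 1e−8 relative error (tested on dozens of random panels). Model
degrees of freedom count slope columns plus the rank of the implicit
dummy block — exact for the first two dimensions via connected components
of their bipartite graph, plus levels−1 for each further dimension — so
standard errors also match the dense regression.

Inference is the CR1 sandwich
`(X'X)⁻¹ [Σ_g X_g'e_g e_g'X_g] (X'X)⁻¹ · G/(G−1) · (N−1)/(N−K)`
on demeaned regressors, with normal 95 % critical values. With every row
its own cluster this reduces exactly to HC1.

**Month-by-city conventions.** The month-by-city fixed effect defaults to
calendar month-of-year × city (seasonal patterns specific to each
location); year-month × city is a configuration switch. Clustering
defaults to month-of-year × city as well: clusters must contain whole
fixed-effect cells, because demeaning redistributes any within-cell error
component across the cells' sub-periods — clustering at a finer level
(year-month) than the absorbed cell leaves a cross-cluster score
correlation that the sandwich omits and understates variance. The finer
convention remains available and is appropriate when the month fixed
effect is itself year-month × city, or when the panel spans many years so
each cell mixes many year-months.

**Interactions.** Demographic interactions expand each bin dummy into
bin × level terms; the marginal effect of a bin for a level is the
corresponding coefficient with its clustered SE (delta rule on a unit
vector). Speaker-constant traits (gender) are validated as constant
within speaker and their main effect is absorbed by the politician fixed
effect; traits that evolve within speaker (age quartile: Q1 ≤ 44,
Q2 45–50, Q3 51–56, Q4 ≥ 57, integer ages; calendar periods 1950–1967,
1968–1985, 1986–2003, 2004–2019) skip that validation. The age grouping
adopts Q4 = ≥ 57, resolving the gap the verbal definition ("above 57")
leaves at exactly 57; fractional ages are not supported. Interaction
models default to politician-level clustering. Empty (bin, level) cells
are reported as missing rows, never dropped silently.

## Synthetic panels and what they do (not) show

The generator emulates the data-generating process the estimator
assumes, with every ingredient stored in a truth record whose per-row
components reconstruct the outcome exactly:

- **Weather**: per city, daily mean temperature is a seasonal sinusoid
  (annual mean drawn from 10–14 °C, amplitude 10–12 °C, July peak) plus
  an AR(1) deviation (φ = 0.7, innovation sd 2.8 °C) — temperate enough
  that all ten bins occur; dew point sits a gamma spread below air
  temperature; wind components are Gaussian; precipitation mixes a point
  mass at zero with gamma wet-day amounts.
- **Speeches** occur on sitting days (weekdays with probability 0.8,
  weekends 0.05 — keeping the day-of-week effect identified), with
  Poisson per-day counts and speakers drawn within each city's
  delegation.
- **Outcome**: baseline 11.1 Flesch-Kincaid grade years (a typical
  parliamentary level) plus bin effects (default 0 on cold and comfort
  bins and a graded warm-side pattern −0.02 / −0.03 / −0.04 / −0.05 on
  18–21 / 21–24 / 24–27 / >27 °C), small control effects, Gaussian
  politician / month-by-city / day-of-week effects (sd 1.0 / 0.3 / 0.1),
  and noise of sd 1.5 split into a shared year-month × city draw
  (variance share ρ = 0.3) plus an idiosyncratic part.

All draws flow from one PCG64 generator, so outputs are bit-identical
per seed across platforms.

The default scale — 48 politicians, 12 cities, 2 years, ≈ 10,000
speeches — is the package's Monte-Carlo validation condition: it runs a
several-hundred-replicate recovery study in minutes on one CPU and
provides 144 month-by-city cells so cluster-robust inference has enough
clusters to be near-nominal. Width (cities) is preferred over length
(years) because the cluster count, not the row count, governs sandwich
accuracy. Validation shows: estimates unbiased within Monte-Carlo
resolution; 95 % interval coverage 90–98 % for the injected warm-bin
effects; null rejection averaging ≈ 6 %. Per-bin null rejection is
mildly liberal (up to ≈ 7.4 %) for bins whose days concentrate in few
clusters — cold bins live in winter cells, the hottest bin in summer
cells — the known finite-cluster downward bias of CR1 with normal
critical values; exceedance-robust small-sample refinements (CR2/CR3,
t(G−1) or effective-df critical values, wild-cluster bootstrap) are
deliberately out of scope.

What passing these tests does **not** show: real speech complexity is
not additive-Gaussian, real weather confounding is richer than three
controls, selection into speaking may itself respond to weather, and the
generator's text module produces statistically controlled but
linguistically meaningless sentences. The synthetic validation
establishes that the estimator recovers what it is pointed at under its
own assumptions — not that those assumptions hold in any real corpus.

Text generation works backwards from target ASL/ASW: sentence counts and
per-word syllable allocations are chosen to land within 0.1 words/sentence
and 0.05 syllables/word of the target, and words are drawn from a small
parliamentary vocabulary annotated by the package's own syllable counter,
making the generate→rescore round trip exact by construction (the
re-scored ASW hits the integer-rounded target, so a Flesch-Kincaid target
is met within 11.8 × 0.05). Words from the abbreviation list are excluded
so re-segmentation preserves sentence boundaries.

## Pipeline mechanics

A run is fully determined by its `RunConfig` (YAML file and/or CLI
flags); referenced columns are validated before any computation. All
intermediates (scored table, exclusion log, weather features, design
metadata, coefficient and marginal-effects tables) are persisted with a
manifest, and stage counts telescope:
`read = estimated + chair + short + unscorable + missing-demographic +
unjoined + missing-field` — asserted on every run. Outputs are
byte-identical across re-runs with the same inputs and config (timings
live only in the report files). Switching the outcome column
(Flesch-Kincaid ↔ Flesch ↔ RIX ↔ component averages) never changes the
estimation sample, so component analyses are comparable row-for-row.
Time trends enter as standardized powers (1 or 1..3) of the whole-week
index since the earliest date in the run. Topic controls enter as dummies
from a supplied categorical column; fitting a topic model is out of
scope, as are plot rendering and corpus-specific ingestion parsers.
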