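# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions.

## Data model and curation

A record is a lot: all specimens of one species from one sampling event. The
canonical container is a pandas DataFrame with fixed columns (species, genus,
class, phylum, year, lat/lon in WGS84 decimal degrees, locality, institution,
catalogue number); a row-level `OccurrenceRecord` dataclass mirrors it.

Ingestion is deliberately forgiving: unparseable coordinates or years become
missing values and never fail a row, because digitized historical data are
full of transcription noise and silent row loss would bias every downstream
count. The collection year is the first four-digit substring in [1750, 2100]
of the event-date field, so full ISO dates and year ranges ("1902–1912")
both resolve; a range takes its first year. A half-missing coordinate pair
is treated as fully missing.

The curation cascade applies seven filters in a fixed order, each recorded as
(stage, n_removed, n_remaining): missing coordinates; outside the study
polygon; missing year; higher taxon not whitelisted; not determined to
species level; infaunal or ≤ 1 cm mean body size; inside an excluded border
region. Removal counts always sum to input minus output, so a run against a
real export can be diffed stage by stage against an independent tally.
Conventions: polygon containment is boundary-inclusive (a record exactly on
the study-area edge is kept — avoids silent loss at region borders);
"species level" means the name has at least two whitespace tokens and the
second is not `sp.`/`spec.`/`indet.`; species missing from the trait table
are retained at the trait stage (unknown is not evidence of exclusion).
Georeferencing is offline only: an in-dataset gazetteer with normalized
(case-folded, whitespace-collapsed) locality keys, never overwriting existing
coordinates. External geocoding services are intentionally out of scope for
reproducibility; a user-supplied gazetteer file covers the same need.
Synonym tables may chain (a→b→c resolves to c); cycles are a hard error.

## Abundance concordance (Poisson factor GLM)

The detectors presume that deposition frequency tracks natural abundance.
The check regresses per-species record counts on an independent ordered
abundance classification with a Poisson log-linear model in the category
factor. For a single factor the MLE is closed-form — the fitted mean of a
category is its sample mean — so the implementation uses the closed form
(with the 0·log 0 = 0 deviance convention for all-zero categories) and the
test suite cross-checks it against an IRLS fit. Significance is the
likelihood-ratio chi-square against the intercept-only model on
(#categories − 1) df. The category is treated as an unordered factor; the
reference level is the first category of the declared order so coefficients
are deterministic. No overdispersion modelling: the check is a coarse
monotonicity screen, not an inferential end point.

## Time-split detectors

The cutoff year (default 1912) is the end of the first large multi-year
survey era; a year equal to the cutoff is historical. The baseline p₀ is the
exact post-cutoff share of all curated lots.

The decline p-value is the exact binomial lower tail, computed by summation
of `scipy.stats.binom.pmf` terms (vectorised over species); no normal
approximation is ever used, so the statistic is exact for the small per-
species counts that dominate collections. α defaults to 0.05, with no
minimum record count (a configurable floor exists but is off) and no
multiple-testing correction by default; Benjamini–Hochberg is available by
flag. The rare-species exclusions (≥10 records, >1 collection year, not
confined to 1977–1990) belong to the first-record screen only — a species
set aside there can still be classified declining, but a neozoa candidate
cannot (its lots are all post-cutoff, so its lower tail is large).

The artefact check quantifies a map inspection: grid the area into 0.5°
cells (configurable), and compute the fraction of a species' post-cutoff
records that fall in cells with at least one pre-cutoff record of any
species. Coverage below 0.5 flags the species as a possible spatio-temporal
artefact. Both numbers are invented quantifications of a visual check and
are always reported alongside the flag, never silently applied. A species
with no georeferenced post-cutoff records has coverage 1.0 (nothing to
question).

## Relative record trends

Annual proportions are computed against class and phylum. Years with fewer
than 5 rank records are dropped (too noisy a denominator); species with
fewer than 10 records overall are not fitted; at least 3 usable years are
required for a fit. Qualifying years where the rank was collected but the
species was not contribute proportion 0 — omitting them would bias slopes
toward zero exactly for the appearing/disappearing species the analysis
targets. (A no-zero-fill comparison is a one-line change in
`annual_proportions`, since the zero rows are the `fillna(0)` join.)

The fit is closed-form OLS of proportion on calendar year (centred for
numerical stability; the slope is unchanged) with a two-sided t-test on
n − 2 df. Degenerate cases: a constant series has slope 0 and p = 1 (no
evidence); a zero-residual fit with nonzero slope is reported as p = 0 and
flagged `degenerate` — a perfect monotone trend is maximal evidence under
this test, and the flag lets users drop such fits if they prefer.

Classification: within each dataset variant (full, and with the exclusion
region removed), the provisional direction is the sign shared by all
significant fits among the two ranks; significant fits with opposing signs
exclude the species as discordant. The final call requires the same
provisional direction in both variants — a trend that vanishes when the
heavily resampled region is excluded is treated as an effort artefact. The
driver uses precomputed year-count tables for speed; the test suite asserts
its equivalence to the per-species public operations.

Known limitation: proportions within a rank are compositional — a strong
true increase in one species depresses every congener's proportion, which
can produce spurious decline calls in small classes. The dual-rank
requirement dampens but does not remove this.

## Synthetic collection process

The generator is a virtual-collector model, not an ecological one. Expected
lot deposition is `effort(year, cell) × abundance(species, year) ×
detectability(species)`, with Poisson lot counts per (species, year, cell)
and uniform jitter of each lot within its 1° cell. Effort is a baseline rate
times multiplicative era pulses, optionally focused on a cell subset.
Abundance trajectories are phenomenological: constant; constant then
geometric decay after a change year; zero then logistic rise after an
arrival year (midpoint 3/growth years past arrival, so the curve starts near
zero); or geometric growth. A war-loss option deletes a fraction of
already-generated records in a year window (off by default). Everything is
reproducible from a single mandatory seed.

The default benchmark emulates the study regime of the North/Baltic Sea
collections at full scale: 240 species in six classes across three phyla,
years 1830–2015, pulses 1868–1888 (×3), 1902–1912 (×6), 1977–1990 (×45) and
1991–2015 (×60, focused on a 6-cell "Dogger Bank" block of the 8×6 grid),
with a baseline of 0.001 lots per cell-year at unit abundance. These
multipliers were chosen analytically so the aggregate post-1912 lot share is
≈ 0.83 and the total collection is ~17–19 k lots over 240 species — the
regime in which the detectors are designed to operate. Planted dynamics: 15
declines (onset 1913–1945, decay 0.85–0.93/yr, expected ≥ 15 lots), 10
introductions (arrivals 1915–1985, logistic growth 0.5, expected ≥ 10 lots
over ≥ 2 years outside 1977–1990), 8 increases (growth 1.02/yr — doubling
every ~35 years, a clear century-scale rise — with base abundance 0.15–0.3
so their effort-weighted record mass matches a common stable species and the
aggregate baseline is not distorted). Stable species draw abundance
1.4·lognormal(0, 0.25) with a floor of 0.9, i.e. every stable species is
expected to appear ≥ ~47 times; this encodes the premise of the first-record
screen that the established fauna is present in the historical record, and
makes a stable species with zero pre-1912 records a < 10⁻³ event.

What the generator does **not** emulate — and what passing recovery tests
therefore cannot show about real data: taxonomic drift and misidentification
(synonymy is exercised only via explicit tables), coastline geometry (the
spatial domain is an abstract grid), depth and gear effects, correlated
multi-species sampling events (cells × years are independent given effort),
duplicate lots, and genuinely rare species with a handful of records (the
benchmark's stable cohort is deliberately well-collected; the detectors'
behaviour on sparse species is covered by the calibration runs instead).

## Calibration and problem sizes

The null calibrations use all-stable collection histories under the pulsed
effort model: 1 000 thinned datasets of 100 species × 30 records for the
decline test (flag rate ≈ 3.4 % at α = 0.05, bound 7.5 %) and 200 simulated
datasets of 60 species for trend calls (≈ 7–9 %, bound 10 % — the mild
inflation over α comes from heteroscedastic proportion noise across years
and is inherent to the OLS-on-proportions procedure). Benchmark recovery is
evaluated over 20 seeds. These sizes were chosen as the smallest runs whose
Monte-Carlo error is well inside the decision margins; the whole suite and
the acceptance script each finish in about a minute on one CPU.

## Pipeline conventions

One YAML config drives every stage; all defaults mirror the study constants
(cutoff 1912, neozoa minimum 10 records, intensive window 1977–1990, 5 rank
records per qualifying year, 10 species records, α = 0.05). Stage failures
abort with the stage name. Outputs are plain CSV/JSON, sorted by species,
with no timestamps, so identical config + seed reproduces byte-identical
tables. Cross-validation is exact set arithmetic on the detected sets;
when a species is corroborated by one source (e.g. an endangered listing)
and contradicted by another (e.g. an external increasing trend),
corroboration wins in the percentages and both memberships are reported
separately in `by_source`.
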