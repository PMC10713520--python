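# Methods

## Data model

One *record* is an original research article with journal, document type,
publication year, a semicolon-delimited author string, one or more raw
corresponding-author address strings, a total citation count, and optional
DOI/page length. The reader accepts tab-delimited UTF-8 exports with WoS
field tags (AU, SO, DT, PY, C1, TC, DI, PG) through a configurable column
map; rows lacking a year or journal are dropped and counted. Multiple
addresses inside one field are separated by `" | "` (a convention of this
package's dialect; single-address records are the common case and
round-trip unchanged).

Author counts default to the number of non-empty `;`-separated tokens,
which is robust to trailing delimiters; the cruder delimiter-count-plus-one
rule is available behind `literal=True`.

Citations per year divide the total citation count by
`reference_year − publication_year`, floored at 1 so that articles
published in the reference year are counted over one year. The reference
year is a free configuration parameter (default 2022) because no single
convention is canonical; it is recorded in the run metadata.

## Geolocation

Addresses are resolved offline against a gazetteer CSV
(`city,country,lat,lng,pop,capital`). Matching is country-first: the
rightmost comma-separated token that canonicalizes to a known country fixes
the country, then the longest token naming a city of that country
(case-insensitive, punctuation-stripped) fixes the city. Same-named cities
in different countries (London UK vs London, Ontario) can therefore never
be merged. No fuzzy matching: precision over recall, and the result is a
pure function of (address, gazetteer). Unresolvable addresses are returned
as `unresolved`, not errors; the pipeline reports the resolution rate.

Country canonicalization uses a small alias table (United States/U.S.A. →
USA; England/Scotland/Wales/Northern Ireland → UK; Peoples R China →
China; …) with unknown names passed through verbatim and flagged. The
continent table merges North and South America into "Americas".

The packaged gazetteer (~160 cities over the 32 study countries, with
approximate coordinates and populations) exists to make the geocoder and
generator deterministic and self-contained; coordinates are carried for
reporting only — no spatial computation is performed on them.

Population normalization (articles per million persons) joins a national
population table, either long format (`country,population`) or World Bank
wide format with a `year` selector. The packaged table holds 2019 values:
the final study year, chosen because published per-million figures
back-solve to populations of that vintage (e.g. Denmark, 182 articles /
5.82 M ≈ 31.3 per million). Countries missing from the table are flagged
and excluded from normalized metrics, never silently zeroed.

## The excess model

Let a *unit* be a country or a (city, country) pair. A record contributes
one article and its full citation count to each distinct unit among its
addresses — once per country even with two addresses there, once in each of
two countries when addresses span both. This makes unit totals sum to more
than the article count, which is stated in the output metadata. Units below
the inclusion threshold (default ≥ 10 articles over the window) are
dropped and the retained coverage fraction reported.

The fit is OLS of `log10(n_articles)` on `log10(total_citations)` across
units. R² equals the squared Pearson correlation of the two log columns and
is direction-independent. Expected articles for a unit are
`10^(a + b·log10(citations))`; excess is `observed − expected` and excess %
is relative to the observed count. Because the intercept absorbs any
constant rescaling of citations, excess is invariant under citations → k ×
citations, which is why citation columns given in thousands need no
special handling.

The regression direction is configurable
(`articles_on_citations` default, or inverting a citations-on-articles
fit). Both were evaluated against the published per-country excess column;
the default is the convention that tracks it closely (the inverse
convention roughly halves the USA excess). Neither reproduces the
published column exactly: back-solving expected = observed − published
excess implies a line (slope ≈ 0.891) slightly different from the OLS fit
on the printed, rounded pairs (slope ≈ 0.894), i.e. the published values
were computed on unrounded source data. The package reports the max
absolute deviation from a supplied printed column rather than pretending to
match it.

The literal index `log10(articles)/log10(citations)` is provided separately
(`iri_literal`, defined for counts > 1); the regression-residual form is
what drives all excess estimates, since the two disagree only in
parameterization, not ranking.

## Statistical toolbox

Rank tests are the unpaired two-sided Mann–Whitney (two groups) and
Kruskal–Wallis (≥ 3); identical groups short-circuit to H = 0 rather than
tripping the tie-correction degeneracy. Multiplicity is handled by
Benjamini–Hochberg within a declared family. Spearman correlation is the
Pearson correlation of average ranks with the t-approximation p-value;
constant inputs are an error, not NaN. Two regression slopes are compared
by pooling both series into one OLS with a group indicator and group × time
interaction and reading the interaction's two-sided t-test.

The journal × country composition test treats, for each country, the
yearly proportions of each journal's output originating from that country
as the samples (10 values per journal per country over a 2010–2019
window), compares journals by Kruskal–Wallis, and BH-adjusts across
countries. This yearly-replicate construction gives the test a proper
sampling unit without requiring article-level resampling.

## Citation network

The citation matrix is aggregated from (citing_country, cited_country, n)
events over the union of countries; duplicate pairs sum. DSCI is the ratio
eq1/eq2 defined in the README; eq2's denominator is by default the total
citations emitted by all countries *other than* α (their self-citations
included). Two alternatives are kept for sensitivity analysis: excluding
those self-citations (`include_diagonal=False`) and a "literal" variant
dividing by α's own external citations. The ratio form is the only
combination under which proportional mixing yields exactly 1 for every
country, which the test suite asserts.

DSCI is undefined (flagged, NaN) for a country receiving no external
citations; a country with zero outgoing citations is an error because eq1
has no meaning for it.

Fingerprint clustering normalizes each citing row to proportions (so big
and small emitters are comparable), then applies Ward-linkage
agglomerative clustering on Euclidean distances — equivalent to the
Ward.D2 criterion — and cuts at a configurable number of clusters
(default 3). SciPy's linkage is deterministic for a fixed input ordering;
permuting input rows permutes the partition identically (asserted as
co-membership equality, since cluster integer labels are arbitrary). The
dendrogram is exported as a Newick string.

## Synthetic generator

The generator emulates the study conditions rather than any particular
dataset: 10 countries with sampling weights proportional to the observed
top-10 article counts (USA ≈ 0.539, UK ≈ 0.178, …), years 2010–2019, three
journals with home countries (USA, UK, Germany) and a 5× home-country
affinity multiplier matching the ~5-fold enrichment observed for UK
journals; per-article citation totals are negative binomial (mean 30,
dispersion 1.2 — heavy-tailed, as citation counts are); default corpus
size 2 000 keeps the full test suite fast, with 10 000 used for recovery
experiments.

Citing events follow a two-component mixture at country granularity: a
citation of an article in country j is domestic with probability
`theta_self` and otherwise drawn from the global allocation (realized
article-count shares). Closed forms under configured weights w:

    E[m[i,j]] = n·wⱼ·μ·(θ·1[i=j] + (1−θ)·wᵢ)
    eq1(α) = θ + (1−θ)·w_α        eq2(α) = (1−θ)·w_α
    DSCI(α) = 1 + θ / ((1−θ)·w_α)
    overall domestic share = θ + (1−θ)·Σ w²

The default `theta_self = 0.62` is set so that the expected overall
domestic share equals the ~74.5 % observed in the study corpus given the
default weights (0.62 + 0.38 × 0.334 ≈ 0.747). Note DSCI falls with
country size at fixed θ — the observed positive DSCI–size correlation
therefore requires θ to grow with size, which the generator does not
impose by default.

Per-country linear trends (`trend_slopes`, articles/year) tilt the
country × year sampling weights around the window midpoint, clipped at
zero. Everything is drawn from `numpy.random.default_rng(seed)`; identical
configs are bit-identical, and the generator returns its own ground-truth
tallies (articles per country/city/journal/year, the realized citation
matrix, and its conditional expectation) so recovery tests can assert
against bookkeeping rather than re-estimation.

What the generator does *not* emulate: article-level citation graphs,
citation accrual over time, city-level productivity differences beyond
population weighting, non-Article document types, and dirty address
strings. Passing recovery tests therefore validate the pipeline's
arithmetic and inference machinery, not robustness to real-world metadata
noise.

## Numerical and procedural choices

- Problem sizes: recovery experiments use 10 000 articles (n of the study
  corpus order); DSCI monotonicity uses a 5-point θ grid × 50 seeds at
  1 000 articles, which keeps the whole suite under a minute while leaving
  country-level cells well populated.
- Citations-per-year denominator floored at 1; reference year explicit.
- Gazetteer duplicate (city, country) rows collapse to the
  highest-population entry; out-of-range coordinates are dropped with a
  row-naming warning.
- Excess flag threshold 10 % of observed articles; inclusion threshold 10
  articles; both configurable and recorded in run metadata.
- Pipeline outputs are plain CSV plus one JSON metadata file; reruns with
  identical config and seed are byte-identical.

## Known limitations

- The published per-country excess column cannot be matched exactly from
  the printed table (see "The excess model"); deviations are reported, not
  hidden.
- Country-level DSCI says nothing about within-country institutional
  self-citation; the matrix granularity is national by construction.
- The offline gazetteer trades recall for precision; real exports with
  free-text addresses would need a richer gazetteer or the optional
  edit-distance matching before resolution rates approach 100 %.
- The composition test's yearly-proportion construction assumes roughly
  stable journal volumes across years; journals with strongly drifting
  volume would dilute its power.
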