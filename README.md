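# geobiblio

Geographic disparity metrics for scholarly publishing. The package takes
Web of Science style publication-metadata exports (or synthetic stand-ins),
geolocates corresponding-author addresses against an offline gazetteer, and
quantifies two kinds of geographic bias in medical publishing:

1. **Publication excess/deficit (the IRI model).** Across publishing units
   (countries or cities), log₁₀(citations) is nearly linear in
   log₁₀(publications). Fitting `log10(articles) ~ log10(citations)` by OLS
   and comparing each unit's observed article count with the fitted
   expectation at its accumulated citations yields a signed *publication
   excess* — how many more (or fewer) articles a country published than its
   citation record predicts. Units with |excess| ≥ 10 % of their output are
   flagged. The literal index form `log10(publications)/log10(citations)`
   is also available (`iri_literal`).

2. **Domestic self-citation (DSCI).** From a citing-country × cited-country
   citation matrix *m*, for country α:

       eq1(α) = m[α,α] / Σⱼ m[α,j]                        (self-citation share)
       eq2(α) = Σ_{i≠α} m[i,α] / Σ_{i≠α} Σⱼ m[i,j]        (external reception share)
       DSCI(α) = eq1(α) / eq2(α)

   Under proportional mixing (every country allocates citations in the same
   proportions) DSCI = 1 exactly; DSCI > 1 quantifies domestic preference.
   Citing-country fingerprints (matrix rows as proportions) are grouped by
   Ward-linkage hierarchical clustering on Euclidean distances.

Around these sit a tab-delimited export reader (WoS field tags AU/SO/DT/
PY/C1/TC/DI/PG), a deterministic gazetteer geocoder with country aliasing
and continent mapping, population normalization (articles per million
persons), yearly trend fits with slope-comparison tests, journal × country
composition tests (Kruskal–Wallis with Benjamini–Hochberg adjustment), and
a fully seeded synthetic generator that produces publication corpora and
citation networks with known country weights, home-journal affinity, and a
domestic-preference parameter θ — so every pipeline stage can be validated
by parameter recovery.

Intended users: meta-scientists and bibliometricians auditing geographic
representation in journal portfolios.

## Worked example

The package ships a keyed-in per-country metrics table for 2010–2019
original articles in five leading general-medicine journals (32 countries
with ≥ 10 articles). Reproduce the regression/excess analysis:

```sh
$ geobiblio table1
countries: 32  total articles: 10613
log-log R^2: 97.15%  slope: 0.8939
flagged |excess| >= 10% (fit): 18
flagged |excess| >= 10% (printed column): 19
USA+UK share of positive excess: 84.7%
Spearman articles/million vs articles: rho=0.694 p=1.1e-05
max |deviation| from printed excess: 155.7 articles
```

Reading: publication count explains ~97 % of the variance in accumulated
citations across countries, yet the residuals are systematic — the USA and
UK together account for ~85 % of all articles published in excess of their
citation-predicted counts, and more than half of the countries deviate by
at least 10 %. Population-normalized output correlates strongly with raw
output (Spearman ρ ≈ 0.69). The table's own published excess column was
derived from unrounded source data, so our fit on the printed (rounded)
pairs deviates from it by up to ~156 articles at the extreme (the USA); the
direction and ranking agree throughout.

A synthetic end-to-end run:

```sh
geobiblio simulate --n-articles 2000 --seed 1 --out sim/
geobiblio all --records sim/records.tsv --citing-events sim/citing_events.csv --out reports/
geobiblio dsci --citing-events sim/citing_events.csv --out reports/
```

This writes `country_metrics.csv`, `excess.csv`, `dsci.csv`,
`clusters.csv`, `trends.csv`, `journal_composition.csv`, a Newick
dendrogram of citation fingerprints, and `run_metadata.json` recording
every convention (regression direction, eq2 variant, reference and
population years, thresholds, seed) needed to re-derive any number.

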