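# newsdx

Disease coverage, sentiment and topic mining for news-media corpora.

News media both reflects and shapes public attention to health: which
diseases get covered, in what tone, and under which themes is a signal
for infodemiology — and, downstream, for questions about unmet medical
needs and research priorities.  `newsdx` turns a raw news corpus into
per-disease-concept, per-period measurements of exactly that.  It is
aimed at researchers in biomedical text mining and epidemiological
surveillance who have (a) a corpus of news articles with dates, (b) a
disease-synonym lexicon keyed by concept identifiers (CUI-like), and
(c) terminology mapping tables down to PheWAS disease concepts.

## What it computes

Given articles grouped into study periods, the pipeline runs:

1. **Cleaning** — six ordered rules strip wire-service noise: agency
   tags ("(Reuters)"), editorial byline sentences ("Editing by …"),
   service comments, hyperlinks (→ `link`), repeated special-character
   runs, and `*`/`>` sentence delimiters; lowercasing happens last.
2. **Mention detection** — dictionary matching on cleaned sentences:
   token-anchored, longest-match-first, non-overlapping (so "cancer"
   is never double-counted inside "lung cancer").
3. **Concept normalization** — synonym → CUI → ICD-9-CM → PheWAS; a
   chain ending in exactly one concept is *definitive*, two or more is
   *ambiguous*; attribution defaults to definitive-only.
4. **Coverage** — for concept *c* in period *p*:
   `coverage(c, p) = 100 · |articles mentioning c| / |articles mentioning any disease|`,
   plus cumulative shares of concept subsets (union of article sets),
   cross-period mean ± SD, and a steady / fluctuating / increasing /
   decreasing trend label.
5. **Sentiment** — per disease-mentioning sentence, lexicon valences
   are rule-adjusted (negation ×(−0.74) within a 3-token window,
   booster ±0.293), summed to *s* and normalized to the compound score
   `s/√(s² + 15)` ∈ (−1, 1); per-concept means are banded
   negative / neutral / positive (default band ±0.05).
6. **Topics** — latent Dirichlet allocation by collapsed Gibbs
   sampling, one model per (concept, period) article group, default
   K = 1: the sampler draws each token's topic from
   `p(z_i = t) ∝ (n_dt + α)(n_wt + β)/(n_t + Vβ)` and reports
   `φ_t(w) = (n_wt + β)/(n_t + Vβ)` as top-50 terms in permille
   (1000·P(w|t)).  Multi-word disease names are concatenated
   (`lung_cancer`) before tokenization; stopword removal,
   lookup-table lemmatization and n-gram (n = 1–4) phrase merging are
   built in.

A synthetic-corpus generator (`newsdx.synthetic`) plants known
mentions, topics, sentiment targets and injected noise, so every stage
is testable against ground truth without any licensed data.
See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a noisy 3-period corpus (1,000 articles per period) and run
the full pipeline:

```bash
newsdx simulate --seed 11 --articles 1000 --out demo/data
newsdx run --corpus demo/data/corpus.jsonl \
           --lexicon demo/data/lexicon.tsv \
           --cui-icd demo/data/cui_icd.tsv \
           --icd-phewas demo/data/icd_phewas.tsv \
           --valence demo/data/valence.tsv \
           --out demo/reports --seed 11
```

which prints:

```
period=1996/1997 n_articles=1000 n_disease_articles=4 rate_pct=0.40 n_concepts=3
period=2008 n_articles=1000 n_disease_articles=6 rate_pct=0.60 n_concepts=3
period=2016 n_articles=1000 n_disease_articles=8 rate_pct=0.80 n_concepts=4
reports=coverage.csv,coverage_trends.csv,resolved_config.json,run_summary.json,run_summary.txt,sentiment.csv,topics.csv
```

One line per period: the corpus size, how many articles mention any
disease, that count as a percentage (the disease-article rate — here
rising 0.40% → 0.80%, mirroring the generator's planted fractions),
and how many distinct PheWAS concepts were found.  `coverage.csv` then
holds the per-concept shares of those disease-mentioning articles:

```
phewas_code,phewas_name,period,n_articles,coverage_pct
136,other infectious diseases,1996/1997,2,50.0
136,other infectious diseases,2008,0,0.0
136,other infectious diseases,2016,3,37.5
165,other malignant neoplasm,1996/1997,1,25.0
...
```

e.g. 2 of the 4 disease-mentioning 1996/1997 articles mention concept
136, a 50.0% coverage.  `sentiment.csv` gives each concept's mean
compound score and band per period (`165 … -0.6,negative`), and
`topics.csv` the ranked topic terms with permille weights.  On this
synthetic corpus the counts match the generator's ground truth
exactly; run `python -m pytest tests/test_acceptance.py` to see those
checks.

The same stages are available as library functions
(`newsdx.clean_text`, `newsdx.find_mentions`, `newsdx.fit_lda`, …) for
use on real corpora: JSON Lines articles, TSV lexicon and mapping
tables, TSV valence lexicon.

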