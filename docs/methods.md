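# Methods

`newsdx` implements a news-media infodemiology pipeline: given a corpus
of news articles spanning named study periods, it measures how much
coverage each disease concept receives, with what sentiment, and under
which topics.  This note records the models, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Pipeline model

Each article passes through five stages:

1. **Cleaning** — an ordered rule chain removes wire-service noise.
2. **Mention detection** — dictionary matching against a disease-synonym
   lexicon, on cleaned sentences.
3. **Concept normalization** — each synonym is resolved through a
   synonym → CUI → ICD-9-CM → PheWAS mapping chain to a set of PheWAS
   disease concepts.
4. **Coverage, sentiment** — per-(concept, period) statistics over the
   attributed articles and the disease-mentioning sentences.
5. **Topic modeling** — one LDA fit per (concept, period) article group.

All stages are pure functions of their inputs plus one seed, so a run is
reproducible byte for byte.

## Cleaning

Six rules, applied in a fixed order: (1) remove agency tags such as
"(Reuters)"; (2) delete sentences starting with editorial byline cues
("Editing by", "Reporting by", "Written by", "Page editor"); (3) delete
sentences containing configured service-comment trigger phrases (the
defaults are three observed wire-service boilerplate phrases — the rule
is a configurable trigger list, not a grammar); (4) replace each URL
(http/https scheme or bare `www.` host) with the single token `link`;
(5) replace runs of ≥ `min_repeat_run` (default 3) identical special
characters with a space, so decorations like `---------------` vanish
without gluing words together; (6) replace the ad-hoc sentence
delimiters `*` and `>` with periods.  Lowercasing runs **last**, because
the byline and comment cues are case-sensitive; whitespace is collapsed
at the end.  Cleaning is total (never raises on article text) and
idempotent; after delimiter replacement, runs of periods are collapsed
to a single period precisely to preserve idempotence.

Sentence splitting is rule-based on `[.?!]` with an abbreviation guard
(single-letter initials, a fixed list of common abbreviations such as
"dr.", "u.s.", "no.") and a no-split-between-digits rule.  A
deterministic, dependency-free splitter is adequate here because the
text it sees is already lowercased and delimiter-normalized.

## Mention detection and concept normalization

Matching is exact-string and dictionary-based: token-boundary anchored,
longest-match-first, left-to-right, non-overlapping, with multi-word
synonyms matching across single spaces.  Longest-match-first prevents
"cancer" being counted inside "lung cancer".  No morphological expansion
or negation detection is attempted — "no evidence of cancer" counts as a
mention.

A synonym's PheWAS set is the union over all its CUIs, all their ICD
codes, and those codes' PheWAS concepts.  The *mapping class* is
`definitive` when the set has exactly one element (one-to-one or
multiple-to-one chains), `ambiguous` for two or more, `unmapped` for
none.  `definitive_fraction` reports definitive / mapped synonyms.
Article attribution defaults to `definitive_only` (ambiguous mentions
count toward the disease-mentioning denominator but toward no concept);
`expand_ambiguous` is available for sensitivity analysis.

## Coverage statistics

Coverage of concept *c* in period *p* is
`100 · |articles mentioning c| / |articles mentioning any disease|`,
making periods of very different corpus sizes comparable.  Cumulative
shares of concept subsets use the **union** of article sets, so an
article mentioning several concepts is not double-counted.  Cross-period
summaries use the arithmetic mean and, by default, the sample SD
(n−1): with only three periods the convention is material, so a
population-SD option is exposed and no headline statistic depends on the
choice.

Trends are labelled by an explicit heuristic (the taxonomy itself is
qualitative): *increasing*/*decreasing* when every consecutive step
moves by more than 5% relative in the same direction; otherwise *steady*
when the coefficient of variation is ≤ 0.25; otherwise *fluctuating*.
The rule is scale-invariant.  Reports round rates to 2 decimals and
coverage/mean/SD to 1 decimal.

## Sentiment

Sentence-level lexicon-and-rule scoring.  Lexicon terms carry valences
in [−4, 4]; the adjusted valences are summed to *s* and squashed to the
compound score `s / sqrt(s² + α)` with α = 15, giving a value in
(−1, 1) that is odd and strictly increasing in *s*; a sentence without
lexicon terms scores exactly 0.  Implemented rules: negation within the
three preceding tokens multiplies the valence by −0.74;
booster/dampener words within that window add ±0.293 toward/away from
the term's sign.  Capitalization and punctuation emphasis rules are
deliberately omitted: the pipeline lowercases text before scoring, so
those cues no longer exist at this stage.

Only disease-mentioning sentences are scored.  A concept's sentiment in
a period is the mean compound over all sentences mentioning it (a
sentence mentioning k concepts contributes to all k means); concepts
with no scored sentences are omitted rather than zero-filled.  Mean
compounds are banded negative/neutral/positive with a configurable
neutral band, default ±0.05.

## Topic modeling

Preprocessing: multi-word disease names are joined into single
underscore tokens (`lung cancer` → `lung_cancer`) using the same
longest-match matcher as mention detection, so compound concepts survive
tokenization; stopwords (shipped standard English list) are removed;
words are lemmatized by a lookup table (irregular-form exceptions plus
plural suffix rules) shipped as data so no model download is needed;
frequent adjacent pairs are merged into phrase tokens over
`ngram_max − 1` passes (default 3, allowing 4-grams) when their
collocation score `(count(ab) − min_count) · N / (count(a) · count(b))`
meets the threshold, scanning left-to-right without overlap.

Inference is collapsed Gibbs sampling: per-token assignments are drawn
from `p(z_i = t) ∝ (n_dt + α)(n_wt + β)/(n_t + Vβ)` with the token's own
counts removed; point estimates are the posterior means
`φ_t(w) = (n_wt + β)/(n_t + Vβ)` and `θ_d(t) = (n_dt + α)/(n_d + Kα)`.
An iterated-conditional-modes variant (`mode="icm"`, argmax instead of
draw) is also provided, matching the greedy per-token update some
descriptions of the algorithm give; Gibbs is the default.  Defaults:
K = 1, α = 50/K, β = 0.01, 500 sweeps, top 50 terms.  With K = 1 every
assignment is forced, the sweep loop is skipped, and φ reduces to the
smoothed unigram distribution `(count(w) + β)/(N + Vβ)` — the fit per
(concept, period) group is then a ranked keyword profile, reported in
permille (1000 · P(w|t)), ties broken lexicographically.  The sweep
kernel is JIT-compiled with numba (with an identical pure-Python
fallback) and driven by a single seeded generator, so runs are
bit-reproducible.

Correctness of the sampler is established three ways: the K = 1 closed
form (exact to 1e-12); exhaustive enumeration of the collapsed joint on
a 2-document, 6-token, K = 2 corpus, against which long-run assignment
frequencies agree within 0.02 over 50,000 sweeps; and generative
recovery — on a planted K = 3 corpus (V = 300, D = 400, document length
120, α = 0.1, β = 0.01, 800 sweeps) the fitted topics match the planted
ones with best-permutation mean cosine ≥ 0.9.

## Synthetic data generator

The generator emulates the statistical structure of archive newswire
corpora so every stage can be tested against known truth without any
external data: ~0.5–1% of articles mention diseases (per-period
fractions default to 0.44%, 0.57%, 0.81% across three periods of 1,000
articles each, labelled 1996/1997, 2008, 2016); article text is drawn
from a planted topic model (θ_d ~ Dirichlet(0.1), K = 3 well-separated
topics over a 300-word vocabulary, 120 tokens per article in 12-token
sentences); disease articles receive one synonym insertion at a recorded
sentence/character position, drawn from a six-concept table that mixes
dominant-steady, fluctuating and rising coverage profiles and single-,
nested- and multi-word synonyms; and raw text is decorated with
wire-service noise (tags, bylines, service comments with hyperlinks,
repeated-character runs, `*`/`>` delimiters), each injection logged.

The background vocabulary is synthetic pronounceable pseudo-words, with
everything used by synonyms, the valence pool, stopwords, negations and
boosters excluded, so insertions never collide with background tokens
and matcher output can be compared with planted mentions *exactly*.

Sentiment planting inserts, next to each mention, one word from a
two-word valence pool whose lone-word compounds straddle the concept's
target by ±0.05; the word is chosen with probability
`p_hi = (target − c_lo)/(c_hi − c_lo)`, so the expected sentence
compound equals the target exactly and the per-concept mean converges
within 0.1 well before 500 sentences.  Pool compounds are clamped to
±0.70 so valences stay within the lexicon's [−4, 4] range.

Noise injection is designed to be exactly reversible by the cleaning
chain: tags and bylines are appended and removed wholly; delimiters
replace existing sentence terminators in place; repeated-character runs
sit between spaces; and hyperlinks ride *inside* removable comment
sentences (dot-free URLs, so sentence segmentation cannot split the
comment).  A bare in-text hyperlink is deliberately not part of this
repertoire, because its replacement leaves a residual `link` token; the
separate `inject_link` helper demonstrates that behaviour.

What the generator does **not** emulate: real English prose and word
frequencies (pseudo-word backgrounds have no Zipfian structure, no
polysemy, no morphological variation), nested discourse (negated or
hypothetical disease mentions), wire metadata (topic codes, datelines),
deduplication of re-edited stories, and sentiment expressed without
lexicon words.  Passing recovery tests therefore demonstrate that the
*mechanics* of each stage are correct under the stated generative
assumptions — not that dictionary matching or lexicon sentiment are
accurate on real newswire text.

## Numerical and design choices

- Dates are ISO-8601; period intervals are closed on both ends.
- Coverage and share percentages are exact rational arithmetic ×100,
  rounded only at report time (2 decimals for rates/shares, 1 for
  coverage).
- θ rows and φ rows sum to 1 within 1e-9 (integer count tables make
  this exact up to float division).
- Ties in topic summaries: lexicographic on the term.  Ties in ICM:
  lowest topic index.
- Degenerate inputs raise typed errors: zero denominators, fewer than
  two periods for a trend, an all-unmapped lexicon, K exceeding the
  token count, an empty vocabulary.
- Problem sizes in the recovery experiments (3,000-article end-to-end
  corpus, 400-document topic recovery, 3,000 scored sentences for
  sentiment, 1,000 noisy articles for cleaning, 100 random mapping
  chains) were chosen as the package's own study conditions: large
  enough that sampling error is far from the pass thresholds, small
  enough to run on a laptop in seconds.

## Known limitations

- Exact-string matching misses morphological variants and abbreviations
  of disease names; dictionary coverage bounds recall.
- With `definitive_only` attribution, ambiguous synonyms never reach a
  concept; with `expand_ambiguous`, they reach every candidate —
  neither resolves the ambiguity.
- K is fixed (default 1) per article group; no perplexity-based model
  selection is performed.
- The trend taxonomy is a reporting heuristic, not a statistical test.
- The sentence splitter's abbreviation list is English-specific and
  finite; unusual abbreviations will over-split.
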