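"""End-to-end orchestration: clean → match → coverage → sentiment → topics.

A single structured run configuration drives all stages; every run writes
its resolved configuration and a file manifest next to the reports so
results are reproducible from the artifacts alone.  All stages are pure
functions of their inputs and the seed, so re-running on identical
inputs reproduces the report files byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cleaning, coverage, sentiment, terminology, topics
from .corpus import Corpus, read_corpus
from .errors import ConfigError
from .terminology import DEFINITIVE_ONLY

__all__ = ["RunConfig", "RunSummary", "run_all", "summarize_run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    corpus_path: Path
    lexicon_path: Path
    cui_icd_path: Path
    icd_phewas_path: Path
    valence_path: Path
    output_dir: Path
    cleaning: cleaning.CleaningConfig = field(default_factory=cleaning.CleaningConfig)
    topics: topics.TopicConfig = field(default_factory=topics.TopicConfig)
    attribution_policy: str = DEFINITIVE_ONLY
    neutral_band: tuple[float, float] = (-0.05, 0.05)
    alpha_norm: float = sentiment.DEFAULT_ALPHA_NORM
    rate_decimals: int = 2
    coverage_decimals: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("corpus_path", "lexicon_path", "cui_icd_path",
                     "icd_phewas_path", "valence_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("corpus_path", "lexicon_path", "cui_icd_path",
                    "icd_phewas_path", "valence_path", "output_dir"):
            if key not in raw:
                raise ConfigError(f"run config missing {key!r}")
            kwargs[key] = Path(raw[key])
        if "cleaning" in raw:
            c = dict(raw["cleaning"])
            for k in ("agency_tags", "byline_prefixes", "comment_patterns"):
                if k in c:
                    c[k] = tuple(c[k])
            if "delimiter_chars" in c:
                c["delimiter_chars"] = frozenset(c["delimiter_chars"])
            kwargs["cleaning"] = cleaning.CleaningConfig(**c)
        if "topics" in raw:
            kwargs["topics"] = topics.TopicConfig(**raw["topics"])
        for key in ("attribution_policy", "alpha_norm", "seed",
                    "rate_decimals", "coverage_decimals"):
            if key in raw:
                kwargs[key] = raw[key]
        if "neutral_band" in raw:
            kwargs["neutral_band"] = tuple(raw["neutral_band"])
        return cls(**kwargs)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["cleaning"]["delimiter_chars"] = sorted(d["cleaning"]["delimiter_chars"])
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d


@dataclass
class RunSummary:
    per_period: list[dict]
    cleaning_report: dict[str, int]
    n_mentions: int
    manifest: list[str]

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_run(
    corpus: Corpus,
    mentions: list[terminology.Mention],
    policy: str = DEFINITIVE_ONLY,
) -> list[dict]:
    """Per-period corpus summary: total articles, disease-mentioning
    articles, their rate in percent, and distinct concepts found."""
    period_of = {a.article_id: a.period for a in corpus.articles}
    rows = []
    for period in corpus.period_labels:
        ids = [m for m in mentions if period_of.get(m.article_id) == period]
        concept_articles, all_ids = terminology.articles_by_concept(ids, policy)
        n_total = len(corpus.articles_in(period))
        n_dis = len(all_ids)
        rows.append(
            {
                "period": period,
                "n_articles": n_total,
                "n_disease_articles": n_dis,
                "rate_pct": coverage.disease_article_rate(n_dis, n_total)
                if n_total > 0
                else 0.0,
                "n_concepts": len(concept_articles),
            }
        )
    return rows


def run_all(config: RunConfig) -> RunSummary:
    """Execute the full pipeline and write the report files.

    Outputs (all under ``config.output_dir``): coverage.csv,
    coverage_trends.csv (when >= 2 periods), sentiment.csv, topics.csv,
    run_summary.json, run_summary.txt, resolved_config.json.  Returns the
    run summary with a complete manifest of the files written."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("load")
        corpus = read_corpus(config.corpus_path)
        lexicon = terminology.load_lexicon(config.lexicon_path)
        chain = terminology.load_chain(config.cui_icd_path, config.icd_phewas_path)
        valences = sentiment.load_valence_lexicon(config.valence_path)
    except Exception as exc:
        raise ConfigError(f"stage 'load' failed: {exc}") from exc

    _stage("clean")
    report = cleaning.CleaningReport()
    clean_map: dict[str, str] = {}
    sentences: dict[str, list[str]] = {}
    for art in corpus.articles:
        text, rep = cleaning.clean_text(art.raw_text, config.cleaning)
        clean_map[art.article_id] = text
        report = report.merge(rep)
        sentences[art.article_id] = cleaning.split_sentences(text)
    corpus = corpus.with_clean_texts(clean_map)
    period_of = {a.article_id: a.period for a in corpus.articles}

    _stage("match")
    mentions = terminology.find_mentions(sentences, lexicon, chain)

    _stage("coverage")
    by_period: dict[str, list[terminology.Mention]] = {p: [] for p in corpus.period_labels}
    for m in mentions:
        by_period[period_of[m.article_id]].append(m)
    concept_articles: dict[str, dict[str, set[str]]] = {}
    denominators: dict[str, int] = {}
    for period in corpus.period_labels:
        per_map, all_ids = terminology.articles_by_concept(
            by_period[period], config.attribution_policy
        )
        if all_ids:
            denominators[period] = len(all_ids)
        for code, ids in per_map.items():
            concept_articles.setdefault(code, {})[period] = ids
    records = (
        coverage.concept_coverage(concept_articles, denominators)
        if denominators
        else []
    )
    cov_df = pd.DataFrame(
        [
            {
                "phewas_code": r.phewas_code,
                "phewas_name": chain.phewas_name(r.phewas_code),
                "period": r.period,
                "n_articles": r.n_articles,
                "coverage_pct": round(r.coverage_pct, config.coverage_decimals),
            }
            for r in records
        ],
        columns=["phewas_code", "phewas_name", "period", "n_articles", "coverage_pct"],
    )
    cov_path = out / "coverage.csv"
    cov_df.to_csv(cov_path, index=False)
    manifest.append(cov_path.name)

    if len(denominators) >= 2:
        trends = coverage.concept_trends(records, list(denominators))
        trend_df = pd.DataFrame(
            [
                {
                    "phewas_code": t.phewas_code,
                    "phewas_name": chain.phewas_name(t.phewas_code),
                    "mean_pct": round(t.mean_pct, config.coverage_decimals),
                    "sd_pct": round(t.sd_pct, config.coverage_decimals),
                    "trend_class": t.trend_class,
                }
                for t in trends
            ],
            columns=["phewas_code", "phewas_name", "mean_pct", "sd_pct", "trend_class"],
        )
        trend_path = out / "coverage_trends.csv"
        trend_df.to_csv(trend_path, index=False)
        manifest.append(trend_path.name)

    _stage("sentiment")
    sent_scores = sentiment.score_mention_sentences(
        sentences, mentions, valences, config.alpha_norm, config.attribution_policy
    )
    concept_sents = sentiment.concept_sentiment(sent_scores, period_of)
    sent_df = pd.DataFrame(
        [
            {
                "phewas_code": cs.phewas_code,
                "period": cs.period,
                "n_sentences": cs.n_sentences,
                "mean_compound": round(cs.mean_compound, 4),
                "band": sentiment.sentiment_band(cs.mean_compound, config.neutral_band),
            }
            for cs in concept_sents
        ],
        columns=["phewas_code", "period", "n_sentences", "mean_compound", "band"],
    )
    sent_path = out / "sentiment.csv"
    sent_df.to_csv(sent_path, index=False)
    manifest.append(sent_path.name)

    _stage("topics")
    topic_cfg = dataclasses.replace(config.topics, seed=config.seed)
    texts = {a.article_id: a.clean_text or "" for a in corpus.articles}
    summaries = topics.topics_per_concept(
        texts, concept_articles, lexicon, topic_cfg
    )
    topic_rows = []
    for code in sorted(summaries):
        for period in sorted(summaries[code]):
            for rank, (term, permille) in enumerate(
                summaries[code][period].terms, start=1
            ):
                topic_rows.append(
                    {
                        "phewas_code": code,
                        "period": period,
                        "rank": rank,
                        "term": term,
                        "permille": round(permille, 2),
                    }
                )
    topic_df = pd.DataFrame(
        topic_rows, columns=["phewas_code", "period", "rank", "term", "permille"]
    )
    topic_path = out / "topics.csv"
    topic_df.to_csv(topic_path, index=False)
    manifest.append(topic_path.name)

    _stage("summarize")
    per_period = summarize_run(corpus, mentions, config.attribution_policy)
    summary = RunSummary(
        per_period=per_period,
        cleaning_report=report.as_dict(),
        n_mentions=len(mentions),
        manifest=[],
    )
    cfg_path = out / "resolved_config.json"
    cfg_path.write_text(
        json.dumps(config.resolved(), sort_keys=True, indent=2), encoding="utf-8"
    )
    manifest.append(cfg_path.name)

    json_path = out / "run_summary.json"
    txt_path = out / "run_summary.txt"
    manifest.extend([json_path.name, txt_path.name])
    summary.manifest = sorted(manifest)
    json_path.write_text(
        json.dumps(summary.as_dict(), sort_keys=True, indent=2), encoding="utf-8"
    )
    lines = ["period\tn_articles\tn_disease_articles\trate_pct\tn_concepts"]
    for row in per_period:
        lines.append(
            f"{row['period']}\t{row['n_articles']}\t{row['n_disease_articles']}"
            f"\t{row['rate_pct']:.2f}\t{row['n_concepts']}"
        )
    lines.append("")
    for k, v in sorted(report.as_dict().items()):
        lines.append(f"{k}={v}")
    txt_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return summary
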