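"""Per-concept, per-period media-coverage statistics.

Coverage of a disease concept in a period is the percentage of
disease-mentioning articles that mention that concept, i.e.
``100 * n_articles(concept) / n_articles(any disease)``.  Normalizing by
the disease-mentioning total (rather than the corpus size) makes periods
of very different corpus sizes comparable.  Cross-period trends are
labelled with a simple taxonomy: steady, fluctuating, increasing,
decreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

from .errors import ConfigError, UndefinedStatisticError

__all__ = [
    "CoverageRecord",
    "ConceptTrend",
    "disease_article_rate",
    "concept_coverage",
    "cumulative_share",
    "mean_sd",
    "classify_trend",
]

STEADY = "steady"
FLUCTUATING = "fluctuating"
INCREASING = "increasing"
DECREASING = "decreasing"


@dataclass(frozen=True)
class CoverageRecord:
    phewas_code: str
    period: str
    n_articles: int
    coverage_pct: float


@dataclass(frozen=True)
class ConceptTrend:
    phewas_code: str
    mean_pct: float
    sd_pct: float
    trend_class: str


def disease_article_rate(n_disease_articles: int, n_total_articles: int) -> float:
    """Percentage of all articles that mention any disease, to 2 decimals.

    E.g. 3516 disease-mentioning articles out of 806,791 -> 0.44.
    """
    if n_total_articles <= 0:
        raise UndefinedStatisticError("total article count must be positive")
    if not 0 <= n_disease_articles <= n_total_articles:
        raise UndefinedStatisticError(
            "disease article count outside [0, total]"
        )
    return round(100.0 * n_disease_articles / n_total_articles, 2)


def concept_coverage(
    concept_articles: Mapping[str, Mapping[str, Set[str]]],
    denominators: Mapping[str, int],
) -> list[CoverageRecord]:
    """Coverage records for every (concept, period) pair.

    ``concept_articles`` maps phewas_code -> period -> article-id set;
    ``denominators`` gives each period's count of articles mentioning any
    disease.  Concepts absent from a period get n_articles = 0.
    """
    for period, denom in denominators.items():
        if denom <= 0:
            raise UndefinedStatisticError(
                f"period {period!r}: zero disease-mentioning denominator"
            )
    records: list[CoverageRecord] = []
    for code in sorted(concept_articles):
        per_period = concept_articles[code]
        for period in denominators:
            ids = per_period.get(period, set())
            n = len(ids)
            records.append(
                CoverageRecord(
                    phewas_code=code,
                    period=period,
                    n_articles=n,
                    coverage_pct=100.0 * n / denominators[period],
                )
            )
    return records


def cumulative_share(
    concept_articles: Mapping[str, Set[str]],
    concept_subset: Iterable[str],
    denominator: int,
) -> float:
    """Percentage of disease-mentioning articles covered by a concept set.

    Counts the *union* of the subset's article sets so an article
    mentioning several concepts is not double-counted; e.g. a union of
    3174 distinct articles over a denominator of 3516 gives 90.27.
    """
    if denominator <= 0:
        raise UndefinedStatisticError("denominator must be positive")
    union: set[str] = set()
    for code in concept_subset:
        union |= set(concept_articles.get(code, set()))
    return round(100.0 * len(union) / denominator, 2)


def mean_sd(pcts: Sequence[float], population: bool = False) -> tuple[float, float]:
    """Arithmetic mean and standard deviation of per-period coverages.

    Sample SD (n-1 denominator) by default; with only three periods the
    convention is material, so a population-SD option is exposed.
    Rounding is left to report time."""
    n = len(pcts)
    if n < 2:
        raise UndefinedStatisticError("need at least two period values")
    mean = sum(pcts) / n
    ddof = 0 if population else 1
    var = sum((x - mean) ** 2 for x in pcts) / (n - ddof)
    return mean, math.sqrt(var)


def classify_trend(
    pcts: Sequence[float],
    rel_tol: float = 0.05,
    cv_threshold: float = 0.25,
) -> str:
    """Label a chronological coverage series.

    Precedence: *increasing* if every step rises by more than ``rel_tol``
    relative; *decreasing* if every step falls likewise; *steady* if the
    coefficient of variation (sample SD / mean) is at most
    ``cv_threshold``; else *fluctuating*.  The rule is scale-invariant.
    """
    if len(pcts) < 2:
        raise ConfigError("need at least two period values")
    if any(p < 0 for p in pcts):
        raise ConfigError("coverage percentages must be non-negative")
    rising = all(b > a * (1.0 + rel_tol) for a, b in zip(pcts, pcts[1:]))
    if rising:
        return INCREASING
    falling = all(b < a * (1.0 - rel_tol) for a, b in zip(pcts, pcts[1:]))
    if falling:
        return DECREASING
    mean, sd = mean_sd(pcts)
    if mean == 0 or sd / mean <= cv_threshold:
        return STEADY
    return FLUCTUATING


def concept_trends(
    records: Iterable[CoverageRecord],
    period_order: Sequence[str],
    rel_tol: float = 0.05,
    cv_threshold: float = 0.25,
    population_sd: bool = False,
) -> list[ConceptTrend]:
    """Cross-period mean, SD and trend class for each concept."""
    by_code: dict[str, dict[str, float]] = {}
    for rec in records:
        by_code.setdefault(rec.phewas_code, {})[rec.period] = rec.coverage_pct
    trends = []
    for code in sorted(by_code):
        series = [by_code[code].get(p, 0.0) for p in period_order]
        mean, sd = mean_sd(series, population=population_sd)
        trends.append(
            ConceptTrend(
                phewas_code=code,
                mean_pct=mean,
                sd_pct=sd,
                trend_class=classify_trend(series, rel_tol, cv_threshold),
            )
        )
    return trends
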