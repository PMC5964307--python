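"""Article and period data types plus line-oriented corpus I/O.

A corpus is a set of news articles, each belonging to one named study
period (e.g. ``"1996/1997"``, ``"2008"``).  On disk a corpus is JSON
Lines, UTF-8, one article object per line — streamable and diff-friendly.
Period date ranges are closed intervals ``[start_date, end_date]``.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import CorpusFormatError

__all__ = [
    "Period",
    "NewsArticle",
    "Corpus",
    "read_corpus",
    "write_corpus",
    "DEFAULT_SCHEMA",
]

#: Default mapping from logical field names to JSON keys.
DEFAULT_SCHEMA: Mapping[str, str] = {
    "id": "id",
    "date": "date",
    "text": "text",
    "period": "period",
    "clean_text": "clean_text",
}


@dataclass(frozen=True)
class Period:
    """A named study period covering the closed date interval
    ``[start_date, end_date]``."""

    label: str
    start_date: _dt.date
    end_date: _dt.date

    def __post_init__(self) -> None:
        if not self.label:
            raise CorpusFormatError("period label must be non-empty")
        if self.start_date > self.end_date:
            raise CorpusFormatError(
                f"period {self.label!r}: start_date {self.start_date} "
                f"after end_date {self.end_date}"
            )

    def contains(self, date: _dt.date) -> bool:
        return self.start_date <= date <= self.end_date


@dataclass
class NewsArticle:
    """One news item.

    ``clean_text`` is absent (``None``) until the cleaning stage has run;
    once present it must contain no uppercase letters.
    """

    article_id: str
    date: _dt.date
    period: str
    raw_text: str
    clean_text: str | None = None

    def __post_init__(self) -> None:
        if not self.article_id:
            raise CorpusFormatError("article_id must be non-empty")
        if self.clean_text is not None and any(c.isupper() for c in self.clean_text):
            raise CorpusFormatError(
                f"article {self.article_id!r}: clean_text contains uppercase"
            )


@dataclass
class Corpus:
    periods: list[Period] = field(default_factory=list)
    articles: list[NewsArticle] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [p.label for p in self.periods]
        if len(labels) != len(set(labels)):
            raise CorpusFormatError("duplicate period labels in corpus")
        by_label = {p.label: p for p in self.periods}
        seen: set[str] = set()
        for art in self.articles:
            if art.article_id in seen:
                raise CorpusFormatError(f"duplicate article id {art.article_id!r}")
            seen.add(art.article_id)
            period = by_label.get(art.period)
            if period is None:
                raise CorpusFormatError(
                    f"article {art.article_id!r}: unknown period {art.period!r}"
                )
            if not period.contains(art.date):
                raise CorpusFormatError(
                    f"article {art.article_id!r}: date {art.date} outside "
                    f"period {art.period!r}"
                )

    @property
    def period_labels(self) -> list[str]:
        return [p.label for p in self.periods]

    def articles_in(self, period_label: str) -> list[NewsArticle]:
        return [a for a in self.articles if a.period == period_label]

    def with_clean_texts(self, clean: Mapping[str, str]) -> "Corpus":
        """Return a copy with ``clean_text`` filled in from an id→text map."""
        arts = [
            replace(a, clean_text=clean.get(a.article_id, a.clean_text))
            for a in self.articles
        ]
        return Corpus(periods=list(self.periods), articles=arts)


def _parse_date(value: str, lineno: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise CorpusFormatError(f"line {lineno}: bad date {value!r}: {exc}") from exc


def read_corpus(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    periods: Sequence[Period] | None = None,
) -> Corpus:
    """Read a JSON Lines corpus, one article per line, order preserved.

    Each record must carry at least id, date and text fields (JSON key
    names configurable through ``schema``).  The period of an article is
    taken from the record's period field if present, else from the first
    of the supplied ``periods`` containing the article date, else the
    article's calendar year.  When ``periods`` is not supplied, period
    date ranges are inferred as the label-wise min/max article dates.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    path = Path(path)

    raw_records: list[tuple[int, dict]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: malformed JSON: {exc}") from exc
            if not isinstance(rec, dict):
                raise CorpusFormatError(f"line {lineno}: record is not an object")
            raw_records.append((lineno, rec))

    supplied = list(periods) if periods is not None else None
    articles: list[NewsArticle] = []
    seen_ids: set[str] = set()
    for lineno, rec in raw_records:
        for logical in ("id", "date", "text"):
            if sch[logical] not in rec:
                raise CorpusFormatError(
                    f"line {lineno}: missing field {sch[logical]!r}"
                )
        art_id = str(rec[sch["id"]])
        if art_id in seen_ids:
            raise CorpusFormatError(f"duplicate article id {art_id!r}")
        seen_ids.add(art_id)
        date = _parse_date(rec[sch["date"]], lineno)
        label = rec.get(sch["period"])
        if label is None:
            if supplied is not None:
                for p in supplied:
                    if p.contains(date):
                        label = p.label
                        break
            if label is None:
                label = str(date.year)
        clean = rec.get(sch["clean_text"])
        articles.append(
            NewsArticle(
                article_id=art_id,
                date=date,
                period=str(label),
                raw_text=str(rec[sch["text"]]),
                clean_text=None if clean is None else str(clean),
            )
        )

    if supplied is not None:
        period_list = supplied
    else:
        bounds: dict[str, tuple[_dt.date, _dt.date]] = {}
        for art in articles:
            lo, hi = bounds.get(art.period, (art.date, art.date))
            bounds[art.period] = (min(lo, art.date), max(hi, art.date))
        period_list = [Period(lbl, lo, hi) for lbl, (lo, hi) in bounds.items()]
    return Corpus(periods=list(period_list), articles=articles)


def write_corpus(
    corpus: Corpus, path: str | Path, schema: Mapping[str, str] | None = None
) -> int:
    """Write a corpus as JSON Lines; returns the number of records written.

    ``read_corpus(write_corpus(c))`` reproduces the articles field for
    field (text preserved exactly, non-ASCII included)."""
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for art in corpus.articles:
            rec = {
                sch["id"]: art.article_id,
                sch["date"]: art.date.isoformat(),
                sch["period"]: art.period,
                sch["text"]: art.raw_text,
            }
            if art.clean_text is not None:
                rec[sch["clean_text"]] = art.clean_text
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True))
            fh.write("\n")
            n += 1
    return n


def iter_period_articles(corpus: Corpus) -> Iterable[tuple[Period, list[NewsArticle]]]:
    for period in corpus.periods:
        yield period, corpus.articles_in(period.label)
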