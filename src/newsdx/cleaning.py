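"""Newswire text cleaning as an ordered, configurable rule chain.

Raw wire copy carries agency tags ("(Reuters)"), trailing editorial
bylines ("Editing by ..."), service comments, hyperlinks, decorative
runs of repeated special characters, and "*"/">" used as ad-hoc
sentence delimiters.  ``clean_text`` strips or normalizes each of these
in a fixed order and lowercases last, because the byline and comment
cues are case-sensitive.  Every rule reports how many edits it made.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .errors import ConfigError

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "clean_text",
    "split_sentences",
]

_DEFAULT_AGENCY_TAGS = ("(Reuters)", "(Reuters Life)")
_DEFAULT_BYLINE_PREFIXES = ("Editing by", "Reporting by", "Written by", "Page editor")
_DEFAULT_COMMENT_PATTERNS = (
    "click on the codes in brackets to see stories",
    "the following statement was released by the rating agency",
    "note to subscribers",
)

# Abbreviations after which a period does not end a sentence.  Entries are
# compared against the lowercased word preceding the period, inner dots
# stripped ("u.s." -> "us").  Any single letter also counts (initials).
_ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "st", "jr", "sr", "prof", "rev", "gen",
        "col", "gov", "sen", "rep", "vs", "etc", "eg", "ie", "cf", "no",
        "inc", "ltd", "co", "corp", "dept", "est", "fig", "jan", "feb",
        "mar", "apr", "jun", "jul", "aug", "sep", "sept", "oct", "nov",
        "dec", "us", "uk", "un",
    }
)

_URL_RE = re.compile(r"(?:https?://|www\.)[^\s<>\"\)\]]+", re.IGNORECASE)


@dataclass(frozen=True)
class CleaningConfig:
    """Parameters of the cleaning rule chain.

    ``min_repeat_run`` is the shortest run of one repeated special
    character that counts as decoration (must be >= 3, so "--" in prose
    survives).  ``link_token`` replaces each full URL and must be a
    single lowercase word.
    """

    agency_tags: tuple[str, ...] = _DEFAULT_AGENCY_TAGS
    byline_prefixes: tuple[str, ...] = _DEFAULT_BYLINE_PREFIXES
    comment_patterns: tuple[str, ...] = _DEFAULT_COMMENT_PATTERNS
    link_token: str = "link"
    min_repeat_run: int = 3
    delimiter_chars: frozenset[str] = frozenset("*>")

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[a-z]+", self.link_token):
            raise ConfigError("link_token must be a single lowercase word")
        if self.min_repeat_run < 3:
            raise ConfigError("min_repeat_run must be >= 3")
        for ch in self.delimiter_chars:
            if len(ch) != 1:
                raise ConfigError("delimiter_chars must be single characters")


@dataclass
class CleaningReport:
    tags_removed: int = 0
    byline_sentences_removed: int = 0
    comments_removed: int = 0
    links_replaced: int = 0
    repeat_runs_removed: int = 0
    delimiters_replaced: int = 0

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        return CleaningReport(
            self.tags_removed + other.tags_removed,
            self.byline_sentences_removed + other.byline_sentences_removed,
            self.comments_removed + other.comments_removed,
            self.links_replaced + other.links_replaced,
            self.repeat_runs_removed + other.repeat_runs_removed,
            self.delimiters_replaced + other.delimiters_replaced,
        )

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _is_abbreviation(text: str, dot_pos: int) -> bool:
    """True if the '.' at dot_pos ends an abbreviation or sits in a number."""
    if 0 < dot_pos < len(text) - 1 and text[dot_pos - 1].isdigit() and text[dot_pos + 1].isdigit():
        return True
    j = dot_pos
    # walk back over the word (letters and inner dots)
    i = j - 1
    while i >= 0 and (text[i].isalpha() or text[i] == "."):
        i -= 1
    word = text[i + 1 : j].lower().replace(".", "")
    if not word:
        return False
    return len(word) == 1 or word in _ABBREVIATIONS


def _segment(text: str, extra_delims: Iterable[str] = ("*", ">")) -> list[str]:
    """Split text into sentence-like segments.

    Boundaries are runs of [.?!] (with an abbreviation/number guard),
    newlines, and any ``extra_delims`` characters.  Each segment keeps
    its trailing [.?!] terminator; delimiter characters themselves are
    kept as their own one-character segments so callers can reassemble
    the text.
    """
    delims = set(extra_delims)
    segments: list[str] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in ".?!":
            # absorb a run of terminators
            j = i
            while j + 1 < n and text[j + 1] in ".?!":
                j += 1
            if ch == "." and j == i and _is_abbreviation(text, i):
                i += 1
                continue
            segments.append(text[start : j + 1])
            start = j + 1
            i = j + 1
        elif ch == "\n" or ch in delims:
            if start < i:
                segments.append(text[start:i])
            segments.append(ch)
            start = i + 1
            i += 1
        else:
            i += 1
    if start < n:
        segments.append(text[start:])
    return segments


def _starts_with_prefix(segment: str, prefixes: tuple[str, ...]) -> bool:
    s = segment.lstrip().lower()
    return any(s.startswith(p.lower()) for p in prefixes)


def clean_text(
    raw: str, config: CleaningConfig | None = None
) -> tuple[str, CleaningReport]:
    """Apply the full cleaning chain to one article's raw text.

    Rule order: agency tags, byline sentences, comment sentences, URL
    replacement, repeated-special-character runs, "*"/">" delimiters,
    lowercasing; trailing whitespace normalization.  Cleaning is total
    (never raises on article text) and idempotent.
    """
    config = config or CleaningConfig()
    report = CleaningReport()
    text = raw

    # 1. agency tags
    for tag in config.agency_tags:
        pattern = re.compile(re.escape(tag), re.IGNORECASE)
        text, n = pattern.subn(" ", text)
        report.tags_removed += n

    # 2./3. sentence-level removals: bylines and comments
    segments = _segment(text, extra_delims=config.delimiter_chars)
    kept: list[str] = []
    for seg in segments:
        if len(seg.strip()) > 1 or seg.strip() not in config.delimiter_chars:
            if _starts_with_prefix(seg, config.byline_prefixes):
                report.byline_sentences_removed += 1
                continue
            low = seg.lower()
            if any(pat.lower() in low for pat in config.comment_patterns):
                report.comments_removed += 1
                continue
        kept.append(seg)
    # segments partition the text, so empty-join reconstructs it exactly
    # (minus removed sentences); whitespace is normalized at the end.
    text = "".join(kept)

    # 4. hyperlinks -> link token
    text, n = _URL_RE.subn(config.link_token, text)
    report.links_replaced += n

    # 5. runs of one repeated special character
    run_re = re.compile(
        r"([^\w\s])\1{%d,}" % (config.min_repeat_run - 1)
    )
    text, n = run_re.subn(" ", text)
    report.repeat_runs_removed += n

    # 6. "*" / ">" delimiters -> period
    for ch in sorted(config.delimiter_chars):
        n = text.count(ch)
        if n:
            text = text.replace(ch, ".")
            report.delimiters_replaced += n
    # collapse period stutter created by delimiter replacement (keeps the
    # chain idempotent: ".." would otherwise count as a repeat run later)
    text = re.sub(r"\.(\s*\.)+", ". ", text)

    # 7. lowercase, then normalize whitespace
    text = text.lower()
    text = re.sub(r"\s+", " ", text).strip()
    return text, report


def split_sentences(clean: str) -> list[str]:
    """Split cleaned text into sentences, keeping terminators.

    Rule-based on [.?!] with an abbreviation guard ("dr.", "u.s.", single
    initials) and no split between digits; deterministic and adequate for
    lowercased, delimiter-normalized text.  Never returns empty sentences.
    """
    out = []
    for seg in _segment(clean, extra_delims=()):
        seg = seg.strip()
        if seg and seg not in {".", "?", "!"}:
            out.append(seg)
    return out
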