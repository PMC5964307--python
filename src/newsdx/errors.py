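"""Exception hierarchy shared across the pipeline."""


class NewsdxError(Exception):
    """Base class for all package errors."""


class CorpusFormatError(NewsdxError):
    """A corpus file is malformed (bad JSON line, duplicate id, bad date)."""


class TableFormatError(NewsdxError):
    """A lexicon or mapping TSV is malformed."""


class ConfigError(NewsdxError):
    """A configuration object or file is invalid."""


class UndefinedStatisticError(NewsdxError):
    """A statistic is requested on inputs for which it is undefined
    (zero denominator, fewer than two periods, no mapped synonyms)."""
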