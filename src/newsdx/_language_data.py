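"""Shipped language data: a standard English stopword list and the
exception table of the lookup lemmatizer.  Both are deliberately small,
plain-Python data so no external model download is ever needed; both are
overridable through the topic-modeling configuration."""

STOPWORDS = frozenset(
    """
    a about above after again against all am an and any are aren't as at
    be because been before being below between both but by can cannot
    can't could couldn't did didn't do does doesn't doing don't down
    during each few for from further had hadn't has hasn't have haven't
    having he her here hers herself him himself his how i if in into is
    isn't it its itself just me more most mustn't my myself no nor not of
    off on once only or other ought our ours ourselves out over own same
    shan't she should shouldn't so some such than that the their theirs
    them themselves then there these they this those through to too under
    until up very was wasn't we were weren't what when where which while
    who whom why will with won't would wouldn't you your yours yourself
    yourselves
    """.split()
)

# Irregular plurals (and a few common irregular forms) the suffix rules
# cannot reach.
LEMMA_EXCEPTIONS = {
    "children": "child",
    "women": "woman",
    "men": "man",
    "people": "person",
    "mice": "mouse",
    "feet": "foot",
    "teeth": "tooth",
    "geese": "goose",
    "lives": "life",
    "wives": "wife",
    "knives": "knife",
    "leaves": "leaf",
    "halves": "half",
    "selves": "self",
    "analyses": "analysis",
    "crises": "crisis",
    "diagnoses": "diagnosis",
    "hypotheses": "hypothesis",
    "theses": "thesis",
    "bacteria": "bacterium",
    "criteria": "criterion",
    "phenomena": "phenomenon",
    "data": "datum",
    "media": "medium",
    "viruses": "virus",
    "vaccines": "vaccine",
}

# Words ending in "s" that are not plurals.
NON_PLURAL_S = frozenset(
    {
        "news", "aids", "diabetes", "measles", "rabies", "series",
        "species", "across", "always", "perhaps", "its", "his", "this",
        "thus", "was", "has", "is", "less", "various", "previous",
        "serious", "famous", "nervous",
    }
)
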