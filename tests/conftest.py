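import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from newsdx.terminology import ConceptLexicon, MappingChain


@pytest.fixture
def small_lexicon() -> ConceptLexicon:
    return ConceptLexicon(
        {
            "lung cancer": frozenset({"C1"}),
            "cancer": frozenset({"C1"}),
            "asthma": frozenset({"C2"}),
            "bird flu": frozenset({"C3"}),
            "flu": frozenset({"C3"}),
            "mystery illness": frozenset({"C1", "C2"}),  # ambiguous
            "orphan syndrome": frozenset({"C9"}),  # chain broken -> unmapped
        }
    )


@pytest.fixture
def small_chain() -> MappingChain:
    return MappingChain(
        cui_to_icd={
            "C1": frozenset({"162.0", "162.1"}),  # multiple-to-one
            "C2": frozenset({"493.0"}),
            "C3": frozenset({"487.0"}),
        },
        icd_to_phewas={
            "162.0": ("165", "other malignant neoplasm"),
            "162.1": ("165", "other malignant neoplasm"),
            "493.0": ("475", "asthma"),
            "487.0": ("481", "influenza"),
        },
    )
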