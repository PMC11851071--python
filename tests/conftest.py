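import pytest

from pvdisprop import (
    DEFAULT_IBD_INDICATIONS,
    SynonymDictionary,
    SyntheticConfig,
    VocabularyMap,
    assemble_cases,
    find_quarter_files,
    generate_dataset,
    read_quarter,
    select_cohort,
    standardize_cases,
)

#: Demo-scale generator settings shared across tests: a couple of planted
#: signals, duplicates and missingness all switched on.
DEMO_CONFIG = dict(
    n_cases=2000,
    seed=7,
    planted_signals={"Acne": 8.0, "Haematochezia": 5.0},
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One generated quarterly extract plus its ground-truth manifest."""
    out = tmp_path_factory.mktemp("synthetic_quarter")
    manifest = generate_dataset(SyntheticConfig(**DEMO_CONFIG), out)
    return out, manifest


@pytest.fixture(scope="session")
def assembled(small_dataset):
    """The small dataset read back, deduplicated and standardized."""
    out, manifest = small_dataset
    quarter = read_quarter(find_quarter_files(out))
    cases, stats = assemble_cases([quarter])
    standardize_cases(cases, SynonymDictionary.default())
    return cases, stats, manifest


@pytest.fixture(scope="session")
def ibd_cohort(assembled):
    cases, _, _ = assembled
    return select_cohort(cases, "upadacitinib", indication_terms=DEFAULT_IBD_INDICATIONS)


@pytest.fixture(scope="session")
def vocab():
    return VocabularyMap.bundled()
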