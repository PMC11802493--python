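import pytest

from faerspv.pipeline import load_tables
from faerspv.preprocess import build_cohort
from faerspv.synthetic import (
    HEM_MALIGNANCY_TERMS,
    TARGET_DRUG_NAMES,
    InjectedSignal,
    default_config,
    generate_cohort,
    make_mini_dictionary,
)


def _build(tmp_path, config, dictionary):
    manifest = generate_cohort(config, tmp_path)
    demo, drug, reac, indi, ther = load_tables(tmp_path)
    universe, cohort, audit = build_cohort(
        demo, drug, reac, indi, ther,
        drug_names=set(TARGET_DRUG_NAMES),
        indication_terms=set(HEM_MALIGNANCY_TERMS),
    )
    return {
        "dir": tmp_path, "config": config, "dictionary": dictionary,
        "manifest": manifest, "universe": universe, "cohort": cohort,
        "audit": audit,
    }


@pytest.fixture(scope="session")
def mini_dict():
    return make_mini_dictionary(22, 5, seed=1)


@pytest.fixture(scope="session")
def injected_pt(mini_dict):
    return mini_dict.pts[0]


@pytest.fixture(scope="session")
def cohort20k(tmp_path_factory, mini_dict, injected_pt):
    """20 000-case cohort with one injected child-only RR=5 signal."""
    cfg = default_config(
        seed=1, dictionary=mini_dict, n_cases=20_000,
        injected_signals=[
            InjectedSignal(pt=injected_pt, stratum="child", risk_ratio=5.0)
        ],
    )
    return _build(tmp_path_factory.mktemp("cohort20k"), cfg, mini_dict)


@pytest.fixture(scope="session")
def null_cohort(tmp_path_factory, mini_dict):
    """4 000-case cohort with no injected signals (type-I checks)."""
    cfg = default_config(seed=3, dictionary=mini_dict, n_cases=4_000)
    return _build(tmp_path_factory.mktemp("null_cohort"), cfg, mini_dict)
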