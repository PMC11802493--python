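#!/usr/bin/env python
"""Screen the synthetic cohort for disproportionality signals.

Builds the deduplicated hematological-malignancy cohort from the tables
written by 01_generate_cohort.py, screens every PT and SOC in each age
stratum with the four algorithms (ROR, PRR, BCPNN, MGPS), and writes the
ranked signal tables under results/.  The injected child-only signal
should come out positive on all four algorithms in the child stratum and
on none in the adult stratum."""

from pathlib import Path

from faerspv.dictionary import MiniDictionary
from faerspv.pipeline import load_tables
from faerspv.preprocess import build_cohort
from faerspv.signal_stats import format_signal_table, screen
from faerspv.synthetic import HEM_MALIGNANCY_TERMS, TARGET_DRUG_NAMES

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    dictionary = MiniDictionary.load(DATA / "pt_soc.txt")
    demo, drug, reac, indi, ther = load_tables(DATA)
    universe, cohort, audit = build_cohort(
        demo, drug, reac, indi, ther,
        drug_names=set(TARGET_DRUG_NAMES),
        indication_terms=set(HEM_MALIGNANCY_TERMS),
    )
    print(f"cohort audit: {audit.as_dict()}")
    RESULTS.mkdir(exist_ok=True)
    for level in ("SOC", "PT"):
        for stratum in ("child", "adult"):
            df = screen(universe, level=level, stratum=stratum,
                        dictionary=dictionary)
            stem = f"signals_{level.lower()}_{stratum}"
            df.to_csv(RESULTS / f"{stem}.csv", index=False)
            pos = df[df["positive"]]
            print(f"\n{level} / {stratum}: {len(pos)} positive of {len(df)} terms")
            if len(pos):
                print(format_signal_table(pos).to_string(index=False))


if __name__ == "__main__":
    main()
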