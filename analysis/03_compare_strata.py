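#!/usr/bin/env python
"""Child-vs-adult comparison on the synthetic cohort.

Reads the screens' inputs again, then writes: volcano rows (log2 ROR vs
FDR-adjusted Fisher p per term and stratum), per-SOC share histogram
data, the demographic summary, and annual report counts, all under
results/."""

from pathlib import Path

from faerspv.dictionary import MiniDictionary
from faerspv.pipeline import load_tables
from faerspv.preprocess import build_cohort
from faerspv.signal_stats import screen
from faerspv.stratified import (
    annual_counts,
    demographics_table,
    soc_shares,
    volcano_rows,
)
from faerspv.synthetic import HEM_MALIGNANCY_TERMS, TARGET_DRUG_NAMES

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    dictionary = MiniDictionary.load(DATA / "pt_soc.txt")
    demo, drug, reac, indi, ther = load_tables(DATA)
    universe, cohort, _ = build_cohort(
        demo, drug, reac, indi, ther,
        drug_names=set(TARGET_DRUG_NAMES),
        indication_terms=set(HEM_MALIGNANCY_TERMS),
    )
    RESULTS.mkdir(exist_ok=True)
    screens = {
        (lvl, st): screen(universe, level=lvl, stratum=st, dictionary=dictionary)
        for lvl in ("SOC", "PT") for st in ("child", "adult")
    }
    volcano = volcano_rows(screens[("PT", "child")], screens[("PT", "adult")])
    volcano.to_csv(RESULTS / "volcano.csv", index=False)
    sig = volcano[volcano["significant"]]
    print(f"volcano: {len(sig)} significant (term, stratum) rows of {len(volcano)}")
    print(sig.to_string(index=False))

    shares = soc_shares(screens[("SOC", "child")], screens[("SOC", "adult")])
    shares.to_csv(RESULTS / "soc_shares.csv", index=False)
    print(f"\nSOC shares sum (child, adult): "
          f"{shares['child_pct'].sum():.1f}, {shares['adult_pct'].sum():.1f}")

    demographics_table(cohort).to_csv(RESULTS / "demographics.csv", index=False)
    annual = annual_counts(cohort)
    annual.to_csv(RESULTS / "annual_counts.csv", index=False)
    print(f"annual counts over {len(annual)} years; total {annual['count'].sum()}")


if __name__ == "__main__":
    main()
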