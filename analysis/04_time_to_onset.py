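#!/usr/bin/env python
"""Time-to-onset analysis of the synthetic target cohort.

Computes event-onset minus therapy-start intervals for cases where both
dates are day-precise and non-inverted, bins them (0-30, 31-60, 61-90,
91-180, 181-360, >360 days), and writes the per-stratum summary and the
exclusion audit under results/."""

from pathlib import Path

from faerspv.dictionary import MiniDictionary
from faerspv.pipeline import load_tables
from faerspv.preprocess import build_cohort
from faerspv.synthetic import HEM_MALIGNANCY_TERMS, TARGET_DRUG_NAMES
from faerspv.time_to_onset import compute_tto, summarize_tto

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    demo, drug, reac, indi, ther = load_tables(DATA)
    _, cohort, _ = build_cohort(
        demo, drug, reac, indi, ther,
        drug_names=set(TARGET_DRUG_NAMES),
        indication_terms=set(HEM_MALIGNANCY_TERMS),
    )
    records, audit = compute_tto(cohort)
    summary = summarize_tto(records)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "tto_summary.csv", index=False)
    with (RESULTS / "tto_exclusions.csv").open("w") as fh:
        fh.write("reason,count\n")
        for reason, count in audit.items():
            fh.write(f"{reason},{count}\n")
    print(f"exclusion audit: {audit}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
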