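#!/usr/bin/env python
"""Generate the working synthetic cohort: 20 000 spontaneous reports with
one injected child-only risk signal (RR = 5) against a 22-SOC x 5-PT
dictionary, written as FAERS-style "$"-delimited tables under
scratch/synthetic/ together with the ground-truth manifest."""

import json
from pathlib import Path

from faerspv.synthetic import (
    InjectedSignal,
    default_config,
    generate_cohort,
    make_mini_dictionary,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "synthetic"
SEED = 1


def main() -> None:
    dictionary = make_mini_dictionary(22, 5, SEED)
    injected_pt = dictionary.pts[0]
    cfg = default_config(
        seed=SEED, dictionary=dictionary, n_cases=20_000,
        injected_signals=[
            InjectedSignal(pt=injected_pt, stratum="child", risk_ratio=5.0)
        ],
    )
    OUT.mkdir(parents=True, exist_ok=True)
    dictionary.save(OUT / "pt_soc.txt")
    (OUT / "config.json").write_text(cfg.model_dump_json(indent=2) + "\n")
    manifest = generate_cohort(cfg, OUT)
    print(f"wrote {OUT}")
    print(json.dumps(manifest["files"], indent=2))
    print(f"injected signal: ({injected_pt!r}, child, RR=5)")
    print(f"ground-truth strata: {manifest['stratum_counts']}")


if __name__ == "__main__":
    main()
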