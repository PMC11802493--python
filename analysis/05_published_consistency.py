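#!/usr/bin/env python
"""Consistency checks against the published study's printed numbers.

Recomputes from the printed counts: the cohort-composition shares
(children/adults/male/professional reporters), the onset-interval bin
shares, the IC = log2(EBGM) relation for the headline rows, and the
joint four-algorithm verdicts over the printed SOC statistics tables."""

import math

from faerspv import published
from faerspv.signal_stats import SignalStatistics, is_positive


def main() -> None:
    t = published.TOTAL_CASES
    print("cohort composition (printed counts):")
    print(f"  children {published.CHILD_CASES}/{t} = "
          f"{100 * published.CHILD_CASES / t:.2f}%")
    print(f"  adults   {published.ADULT_CASES}/{t} = "
          f"{100 * published.ADULT_CASES / t:.2f}%")
    print(f"  male     {published.MALE_CASES}/{t} = "
          f"{100 * published.MALE_CASES / t:.2f}%")
    prof = sum(c + a for c, a in published.PROFESSIONAL_COUNTS.values())
    print(f"  professional reporters {prof}/{t} = {100 * prof / t:.2f}%")

    print("\ntime-to-onset bins (printed counts):")
    for label, n in published.TTO_BIN_COUNTS.items():
        print(f"  {label} d: {n}/{published.TTO_TOTAL} = "
              f"{100 * n / published.TTO_TOTAL:.2f}%")

    print("\nIC = log2(EBGM) on the headline rows:")
    for label, (ebgm, ic) in published.IC_EBGM_PAIRS.items():
        print(f"  {label}: log2({ebgm}) = {math.log2(ebgm):.2f} (printed IC {ic})")

    print("\njoint verdicts over the printed SOC tables:")
    for name, rows in (("children", published.CHILD_SOC_ROWS),
                       ("adults", published.ADULT_SOC_ROWS)):
        positives = []
        for r in rows:
            s = SignalStatistics(
                ror=r.ror, ror_lo95=r.ror_lo95, ror_hi95=r.ror_hi95,
                prr=r.prr, chi2=r.chi2, ic=r.ic, ic025=r.ic025,
                ebgm=r.ebgm, ebgm05=r.ebgm05,
            )
            if is_positive(s, a=r.a).positive:
                positives.append(r.term)
        print(f"  {name}: {positives}")


if __name__ == "__main__":
    main()
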