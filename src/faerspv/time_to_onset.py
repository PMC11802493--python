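"""Time-to-onset of adverse events.

The interval is the calendar difference in days between the event onset
date (EVENT_DT) and the therapy start date (START_DT).  Reports with a
missing or inaccurate date on either side are excluded: "inaccurate"
covers partial precision (month- or year-only tokens) and onsets that
precede the therapy start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import CaseReport

DEFAULT_BIN_EDGES = (30, 60, 90, 180, 360)

REASON_MISSING = "missing"
REASON_PARTIAL = "partial-precision"
REASON_NEGATIVE = "negative-interval"


@dataclass(frozen=True)
class OnsetRecord:
    case_id: str
    stratum: str
    days: int
    bin: str


def bin_label(lo: int, hi: int | None) -> str:
    return f"{lo}-{hi}" if hi is not None else f">{lo}"


def bin_edges_to_labels(edges: Sequence[int] = DEFAULT_BIN_EDGES) -> List[str]:
    labels = []
    lo = 0
    for hi in edges:
        labels.append(bin_label(lo, hi))
        lo = hi + 1
    labels.append(bin_label(edges[-1], None))
    return labels


def bin_tto(days: int, edges: Sequence[int] = DEFAULT_BIN_EDGES) -> str:
    """Closed integer bins 0-30, 31-60, 61-90, 91-180, 181-360, >360."""
    if days < 0:
        raise ValueError("negative interval should have been excluded upstream")
    lo = 0
    for hi in edges:
        if days <= hi:
            return bin_label(lo, hi)
        lo = hi + 1
    return bin_label(edges[-1], None)


def compute_tto(
    cases: Sequence[CaseReport], edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> Tuple[List[OnsetRecord], Dict[str, int]]:
    """Onset records plus an exclusion audit keyed by reason.

    A case is included only when both EVENT_DT and START_DT parse at day
    precision and the event does not precede the start.
    """
    records: List[OnsetRecord] = []
    audit = {REASON_MISSING: 0, REASON_PARTIAL: 0, REASON_NEGATIVE: 0, "included": 0}
    for case in cases:
        ev, st = case.event_dt, case.therapy_start
        if ev is None or st is None or (ev.precision == "invalid") or (
            st.precision == "invalid"
        ):
            audit[REASON_MISSING] += 1
            continue
        if not (ev.is_day and st.is_day):
            audit[REASON_PARTIAL] += 1
            continue
        days = (ev.date - st.date).days
        if days < 0:
            audit[REASON_NEGATIVE] += 1
            continue
        audit["included"] += 1
        records.append(
            OnsetRecord(case.case_id, case.stratum, days, bin_tto(days, edges))
        )
    return records, audit


def summarize_tto(
    records: Sequence[OnsetRecord], edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Per-stratum n, median days, and per-bin counts and percentages.

    The median is the standard even/odd-n sample median.  An 'all'
    stratum row aggregates everything.
    """
    labels = bin_edges_to_labels(edges)
    strata = sorted({r.stratum for r in records})
    rows = []
    for stratum in strata + ["all"]:
        sub = [r for r in records if stratum == "all" or r.stratum == stratum]
        n = len(sub)
        row: dict = {"stratum": stratum, "n": n}
        row["median_days"] = float(np.median([r.days for r in sub])) if n else np.nan
        for label in labels:
            k = sum(r.bin == label for r in sub)
            row[f"n {label}"] = k
            row[f"pct {label}"] = round(100.0 * k / n, 2) if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
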