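"""Child-vs-adult comparison outputs.

Volcano-plot rows (log2 ROR against FDR-adjusted Fisher p-values),
per-SOC share histogram data, the demographic summary table, and annual
report counts.
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ADULT, CHILD, CaseReport
from .signal_stats import ContingencyTable

logger = logging.getLogger(__name__)


def fisher_p(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed that of the observed table (with a small
    relative tolerance against floating-point ties).
    """
    row1 = t.a + t.b
    col1 = t.a + t.c
    N = t.N
    rv = stats.hypergeom(N, col1, row1)
    k_lo = max(0, row1 + col1 - N)
    k_hi = min(row1, col1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = rv.pmf(ks)
    p_obs = rv.pmf(t.a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def bh_adjust(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg q-values, order-preserving w.r.t. the input."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return list(q)


def volcano_rows(
    child_screen: pd.DataFrame,
    adult_screen: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One row per (term, stratum) with log2 ROR, Fisher p and BH q.

    The BH adjustment is applied jointly across both strata.  Rows whose
    ROR is undefined (zero cell) are omitted and logged.
    """
    frames = []
    for stratum, df in ((CHILD, child_screen), (ADULT, adult_screen)):
        part = df[["term", "a", "b", "c", "d", "ror"]].copy()
        part["stratum"] = stratum
        frames.append(part)
    both = pd.concat(frames, ignore_index=True)
    defined = both["ror"].notna() & (both["ror"] > 0)
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("volcano: %d rows with undefined ROR omitted", n_dropped)
    both = both[defined].reset_index(drop=True)
    pvals = [
        fisher_p(ContingencyTable(int(r.a), int(r.b), int(r.c), int(r.d)))
        for r in both.itertuples()
    ]
    both["log2_ror"] = np.log2(both["ror"])
    both["p_value"] = pvals
    both["q_value"] = bh_adjust(pvals)
    both["significant"] = both["q_value"] < q_threshold
    return both[
        ["term", "stratum", "a", "log2_ror", "p_value", "q_value", "significant"]
    ]


def soc_shares(child_screen: pd.DataFrame, adult_screen: pd.DataFrame) -> pd.DataFrame:
    """Per-SOC percentage of each stratum's SOC-event total.

    Input frames are SOC-level screens (the ``a`` column counts distinct
    (case, SOC) pairs for the target drug).  SOCs present in only one
    stratum are tagged ``exclusive``.
    """
    child = child_screen.set_index("term")["a"]
    adult = adult_screen.set_index("term")["a"]
    socs = sorted(set(child.index) | set(adult.index))
    child_tot = float(child.sum()) or 1.0
    adult_tot = float(adult.sum()) or 1.0
    rows = []
    for soc in socs:
        ca = int(child.get(soc, 0))
        aa = int(adult.get(soc, 0))
        rows.append({
            "soc": soc,
            "child_pct": 100.0 * ca / child_tot,
            "adult_pct": 100.0 * aa / adult_tot,
            "group": "shared" if (ca > 0 and aa > 0) else "exclusive",
        })
    return pd.DataFrame(rows)


WEIGHT_BINS = ((None, 50.0, "<50"), (50.0, 100.0, "50-100"), (100.0, None, ">100"))
PROFESSIONAL_OCCUPATIONS = ("MD", "PH", "HP")  # physician, pharmacist, other HCP


def _pct(n: int, total: int) -> float:
    return 100.0 * n / total if total else 0.0


def demographics_table(
    cases: Sequence[CaseReport], top_k_countries: int = 8
) -> pd.DataFrame:
    """Per-stratum demographic summary: sex, weight bins, reporter
    country (top-k + Other + missing) and reporter type, with
    within-stratum percentages."""
    strata = (CHILD, ADULT)
    groups = {s: [c for c in cases if c.stratum == s] for s in strata}
    totals = {s: len(groups[s]) for s in strata}

    rows = []

    def add(characteristic, category, counter):
        row = {"characteristic": characteristic, "category": category}
        for s in strata:
            n = counter(groups[s])
            row[f"{s}_n"] = n
            row[f"{s}_pct"] = round(_pct(n, totals[s]), 2)
        rows.append(row)

    add("ADEs", "total", len)
    for code, label in (("M", "Male"), ("F", "Female")):
        add("Sex", label, lambda g, c=code: sum(x.sex == c for x in g))
    add("Sex", "Data missing",
        lambda g: sum(x.sex not in ("M", "F") for x in g))

    for lo, hi, label in WEIGHT_BINS:
        def counter(g, lo=lo, hi=hi):
            return sum(
                x.weight_kg is not None
                and (lo is None or x.weight_kg >= lo)
                and (hi is None or x.weight_kg < hi)
                for x in g
            )
        add("Weight (kg)", label, counter)
    add("Weight (kg)", "Data missing", lambda g: sum(x.weight_kg is None for x in g))

    country_counts: dict = {}
    for c in cases:
        if c.reporter_country:
            country_counts[c.reporter_country] = country_counts.get(c.reporter_country, 0) + 1
    top = sorted(country_counts, key=lambda k: (-country_counts[k], k))[:top_k_countries]
    for country in top:
        add("Reporter country", country,
            lambda g, co=country: sum(x.reporter_country == co for x in g))
    add("Reporter country", "Other",
        lambda g: sum(x.reporter_country is not None and x.reporter_country not in top
                      for x in g))
    add("Reporter country", "Data missing",
        lambda g: sum(x.reporter_country is None for x in g))

    for code, label in (("MD", "Physician"), ("PH", "Pharmacist"),
                        ("HP", "Health-professional"), ("CN", "Consumer")):
        add("Reporter type", label, lambda g, c=code: sum(x.occupation == c for x in g))
    add("Reporter type", "Data missing",
        lambda g: sum(x.occupation not in ("MD", "PH", "HP", "CN") for x in g))

    return pd.DataFrame(rows)


def annual_counts(cases: Sequence[CaseReport]) -> pd.DataFrame:
    """Case counts by FDA receipt year; unparseable years go to 'unknown'."""
    buckets: dict = {}
    for c in cases:
        tok = c.fda_dt or ""
        year = tok[:4] if len(tok) >= 4 and tok[:4].isdigit() else "unknown"
        buckets[year] = buckets.get(year, 0) + 1
    rows = [{"year": y, "count": n} for y, n in sorted(buckets.items())]
    return pd.DataFrame(rows, columns=["year", "count"])
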