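"""Deduplication and cohort filtering of spontaneous reports.

Turns raw FAERS-style tables into analysis-ready :class:`CaseReport`
objects: one record per case (the latest version wins), restricted to the
target drug as primary suspect and to the indication list of interest,
with ages normalized to years and each case assigned to a child/adult
stratum (missing ages are excluded from the stratified comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .dictionary import MiniDictionary, UNMAPPED_SOC
from .io import (
    DemographicRecord,
    DrugRecord,
    IndicationRecord,
    PartialDate,
    ReactionRecord,
    TherapyRecord,
    parse_partial_date,
)

logger = logging.getLogger(__name__)

#: age-unit code -> factor converting the stored value to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

CHILD, ADULT, EXCLUDED = "child", "adult", "excluded"
DEFAULT_AGE_CUTOFF = 18.0


@dataclass
class CaseReport:
    """One deduplicated safety report."""

    case_id: str
    primary_id: str
    fda_dt: Optional[str]
    event_dt: PartialDate
    age_years: Optional[float]
    stratum: str
    sex: Optional[str]
    weight_kg: Optional[float]
    reporter_country: Optional[str]
    occupation: Optional[str]
    drugs: List[DrugRecord] = field(default_factory=list)
    reactions: List[str] = field(default_factory=list)
    indications: List[str] = field(default_factory=list)
    therapy_start: Optional[PartialDate] = None
    is_target: bool = False


def _pid_sort_key(pid: str) -> Tuple:
    # numeric IDs compare numerically; otherwise lexicographic
    return (0, int(pid), "") if pid.isdigit() else (1, 0, pid)


def deduplicate(demo: Iterable[DemographicRecord]) -> List[DemographicRecord]:
    """Keep one version per case: latest FDA_DT, ties to the higher PRIMARYID.

    Idempotent; preserves first-seen case order.
    """
    best: Dict[str, DemographicRecord] = {}
    order: List[str] = []
    for rec in demo:
        cur = best.get(rec.case_id)
        if cur is None:
            best[rec.case_id] = rec
            order.append(rec.case_id)
            continue
        key_new = (rec.fda_dt or "", _pid_sort_key(rec.primary_id))
        key_cur = (cur.fda_dt or "", _pid_sort_key(cur.primary_id))
        if key_new > key_cur:
            best[rec.case_id] = rec
    return [best[cid] for cid in order]


def normalize_age(age: Optional[float], unit: Optional[str]) -> Optional[float]:
    """Convert an (age, unit-code) pair to years.

    A missing unit with a present age is assumed to be years; negative
    ages are treated as missing (and logged).
    """
    if age is None:
        return None
    if age < 0:
        logger.warning("negative age %r treated as missing", age)
        return None
    factor = AGE_UNIT_TO_YEARS.get((unit or "YR").upper())
    if factor is None:
        logger.warning("unknown age unit %r; assuming years", unit)
        factor = 1.0
    return age * factor


def assign_stratum(age_years: Optional[float], cutoff: float = DEFAULT_AGE_CUTOFF) -> str:
    """child if age < cutoff, adult if age >= cutoff, excluded if missing."""
    if age_years is None:
        return EXCLUDED
    return CHILD if age_years < cutoff else ADULT


def _normalize_name(name: str) -> str:
    return name.strip().casefold()


def assemble_cases(
    demo: Iterable[DemographicRecord],
    drugs: Iterable[DrugRecord],
    reactions: Iterable[ReactionRecord],
    indications: Iterable[IndicationRecord],
    therapies: Iterable[TherapyRecord] = (),
    age_cutoff: float = DEFAULT_AGE_CUTOFF,
) -> List[CaseReport]:
    """Deduplicate and join the per-table records into CaseReports.

    Ancillary rows are joined on the *retained* version's PRIMARYID, so
    rows belonging to superseded versions are dropped with them.
    """
    kept = deduplicate(demo)
    by_pid: Dict[str, CaseReport] = {}
    cases: List[CaseReport] = []
    for rec in kept:
        age_years = normalize_age(rec.age, rec.age_unit)
        case = CaseReport(
            case_id=rec.case_id,
            primary_id=rec.primary_id,
            fda_dt=rec.fda_dt,
            event_dt=parse_partial_date(rec.event_dt),
            age_years=age_years,
            stratum=assign_stratum(age_years, age_cutoff),
            sex=rec.sex,
            weight_kg=rec.weight_kg,
            reporter_country=rec.reporter_country,
            occupation=rec.occupation,
        )
        by_pid[rec.primary_id] = case
        cases.append(case)
    for d in drugs:
        case = by_pid.get(d.primary_id)
        if case is not None:
            case.drugs.append(d)
    for r in reactions:
        case = by_pid.get(r.primary_id)
        if case is not None:
            case.reactions.append(r.pt)
    for i in indications:
        case = by_pid.get(i.primary_id)
        if case is not None:
            case.indications.append(i.indication_pt)
    for t in therapies:
        case = by_pid.get(t.primary_id)
        if case is not None and case.therapy_start is None:
            case.therapy_start = parse_partial_date(t.start_dt)
    for case in cases:
        if case.therapy_start is None:
            case.therapy_start = PartialDate(None, "invalid")
    return cases


def filter_target_drug(
    cases: Sequence[CaseReport], names: Set[str], role: str = "PS"
) -> List[CaseReport]:
    """Keep cases with >=1 drug whose normalized name is in *names* and
    whose role code matches (exact match after case-folding/trimming)."""
    if not names:
        raise ValueError("target drug name set must be non-empty")
    wanted = {_normalize_name(n) for n in names}
    return [
        c
        for c in cases
        if any(_normalize_name(d.drug_name) in wanted and d.role == role for d in c.drugs)
    ]


def filter_indication(
    cases: Sequence[CaseReport], term_list: Set[str]
) -> List[CaseReport]:
    """Keep cases with >=1 indication PT in *term_list* (normalized)."""
    if not term_list:
        raise ValueError("indication term list must be non-empty")
    wanted = {_normalize_name(t) for t in term_list}
    return [
        c for c in cases if any(_normalize_name(t) in wanted for t in c.indications)
    ]


def mark_target(
    cases: Sequence[CaseReport], names: Set[str], role: str = "PS"
) -> List[CaseReport]:
    """Set ``is_target`` on every case (target-drug exposure flag)."""
    if not names:
        raise ValueError("target drug name set must be non-empty")
    wanted = {_normalize_name(n) for n in names}
    for c in cases:
        c.is_target = any(
            _normalize_name(d.drug_name) in wanted and d.role == role for d in c.drugs
        )
    return list(cases)


def map_pt_to_soc(
    reactions: Sequence[str], dictionary: MiniDictionary
) -> List[Tuple[str, str]]:
    """Annotate each PT with its SOC; unknown PTs go to the UNMAPPED SOC."""
    out = []
    n_unmapped = 0
    for pt in reactions:
        soc = dictionary.soc_of(pt)
        if soc == UNMAPPED_SOC:
            n_unmapped += 1
        out.append((pt, soc))
    if n_unmapped:
        logger.warning("%d of %d PTs not in the dictionary", n_unmapped, len(reactions))
    return out


def case_socs(case: CaseReport, dictionary: MiniDictionary) -> Set[str]:
    return {dictionary.soc_of(pt) for pt in case.reactions}


@dataclass
class FilterAudit:
    """Counts dropped at each cohort-building stage (flowchart-style)."""

    n_raw_versions: int = 0
    n_deduplicated: int = 0
    n_after_drug_filter: int = 0
    n_after_indication_filter: int = 0
    n_child: int = 0
    n_adult: int = 0
    n_age_excluded: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_cohort(
    demo,
    drugs,
    reactions,
    indications,
    therapies,
    drug_names: Set[str],
    indication_terms: Set[str],
    role: str = "PS",
    age_cutoff: float = DEFAULT_AGE_CUTOFF,
) -> Tuple[List[CaseReport], List[CaseReport], FilterAudit]:
    """Full cohort construction.

    Returns ``(universe, cohort, audit)`` where *universe* is every
    deduplicated case passing the indication filter (the disproportionality
    background) with ``is_target`` flagged, and *cohort* is the
    target-drug subset.
    """
    demo = list(demo)
    audit = FilterAudit(n_raw_versions=len(demo))
    cases = assemble_cases(demo, drugs, reactions, indications, therapies, age_cutoff)
    audit.n_deduplicated = len(cases)
    universe = filter_indication(cases, indication_terms)
    audit.n_after_indication_filter = len(universe)
    mark_target(universe, drug_names, role)
    cohort = [c for c in universe if c.is_target]
    audit.n_after_drug_filter = len(cohort)
    audit.n_child = sum(c.stratum == CHILD for c in cohort)
    audit.n_adult = sum(c.stratum == ADULT for c in cohort)
    audit.n_age_excluded = sum(c.stratum == EXCLUDED for c in cohort)
    return universe, cohort, audit
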