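"""Synthetic FAERS-like cohorts with known ground-truth signals.

Emulates the quarterly "$"-delimited file set at a scale a laptop can
screen: per-case demographics (mixed age units, configurable missing-age
fraction), multi-drug records with role codes, multi-PT reactions drawn
from a background reporting distribution, hematological-malignancy
indications, therapy start dates with configurable missingness and
partial precision, duplicate case versions exercising both branches of
the deduplication rule, and injected (PT, stratum, risk-ratio)
drug-event associations whose recovery downstream can be asserted.

Same seed + same config => byte-identical output files.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from . import io as fio
from .dictionary import MiniDictionary
from .preprocess import assign_stratum, normalize_age

TARGET_DRUG_NAMES = ("VORICONAZOLE", "VFEND")

HEM_MALIGNANCY_TERMS = (
    "acute myeloid leukaemia",
    "acute lymphocytic leukaemia",
    "chronic myeloid leukaemia",
    "chronic lymphocytic leukaemia",
    "multiple myeloma",
    "hodgkin's disease",
    "non-hodgkin's lymphoma",
    "myelodysplastic syndrome",
)

OTHER_INDICATION_TERMS = (
    "aspergillosis",
    "pneumonia",
    "diabetes mellitus",
    "hypertension",
)

_COUNTRIES = ("US", "FR", "DE", "JP", "IT", "PL", "CN", "NL", "GB", "IN")
_COUNTRY_P = (0.30, 0.15, 0.07, 0.07, 0.05, 0.04, 0.04, 0.04, 0.12, 0.12)
_OCCUPATIONS = ("MD", "PH", "HP", "CN", None)
_OCCUPATION_P = (0.31, 0.04, 0.53, 0.10, 0.02)
_SEXES = ("M", "F", None)
_SEX_P = (0.60, 0.37, 0.03)

_EPOCH = _dt.date(2004, 1, 1)
_SPAN_DAYS = (_dt.date(2024, 3, 31) - _EPOCH).days


class InjectedSignal(BaseModel):
    pt: str
    stratum: Literal["child", "adult", "both"]
    risk_ratio: float = Field(ge=0.0)


class TTODistribution(BaseModel):
    """Right-skewed onset-minus-start distribution, in days."""

    name: Literal["lognormal"] = "lognormal"
    median_days: float = Field(default=10.0, gt=0.0)
    sigma: float = Field(default=1.1, gt=0.0)


class GeneratorConfig(BaseModel):
    n_cases: int = Field(default=5000, gt=0)
    frac_target_drug: float = Field(default=0.10, ge=0.0, le=1.0)
    frac_children: float = Field(default=0.19, ge=0.0, le=1.0)
    frac_missing_age: float = Field(default=0.11, ge=0.0, le=1.0)
    frac_duplicates: float = Field(default=0.05, ge=0.0, le=1.0)
    frac_missing_start_date: float = Field(default=0.5, ge=0.0, le=1.0)
    frac_partial_start_date: float = Field(default=0.1, ge=0.0, le=1.0)
    frac_hem_indication: float = Field(default=1.0, ge=0.0, le=1.0)
    n_other_drugs: int = Field(default=25, gt=0)
    baseline_pt_probs: Dict[str, float]
    injected_signals: List[InjectedSignal] = Field(default_factory=list)
    tto_distribution: TTODistribution = Field(default_factory=TTODistribution)
    seed: int = 0

    @field_validator("baseline_pt_probs")
    @classmethod
    def _probs_open_unit(cls, v):
        if not v:
            raise ValueError("baseline_pt_probs must be non-empty")
        for pt, p in v.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"baseline probability for {pt!r} must be in (0,1)")
        return v

    @model_validator(mode="after")
    def _signals_refer_to_known_pts(self):
        for sig in self.injected_signals:
            if sig.pt not in self.baseline_pt_probs:
                raise ValueError(
                    f"injected_signals: PT {sig.pt!r} not in baseline_pt_probs"
                )
        return self


def make_mini_dictionary(n_soc: int, pts_per_soc: int, seed: int = 0) -> MiniDictionary:
    """A partition of n_soc * pts_per_soc synthetic PTs into SOCs.

    PT names carry their SOC index so mappings stay readable; the seed
    only shuffles which PT names exist (kept for interface symmetry).
    """
    if n_soc < 1 or pts_per_soc < 1:
        raise ValueError("n_soc and pts_per_soc must be >= 1")
    mapping = {}
    for s in range(1, n_soc + 1):
        soc = f"soc {s:02d}"
        for p in range(1, pts_per_soc + 1):
            mapping[f"pt {s:02d}.{p:02d}"] = soc
    return MiniDictionary(mapping)


def default_config(seed: int = 0, dictionary: Optional[MiniDictionary] = None,
                   **overrides) -> GeneratorConfig:
    """Study-condition defaults over a 22-SOC x 5-PT dictionary.

    Background reporting probabilities are drawn once (from *seed*) in
    0.005-0.04 so that a few dozen events land in each stratum at the
    default cohort size.
    """
    if dictionary is None:
        dictionary = make_mini_dictionary(22, 5, seed)
    rng = np.random.default_rng(seed)
    pts = dictionary.pts
    probs = rng.uniform(0.005, 0.04, size=len(pts))
    baseline = {pt: float(p) for pt, p in zip(pts, probs)}
    cfg = dict(baseline_pt_probs=baseline, seed=seed)
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def _date_token(day_offset: int) -> str:
    return (_EPOCH + _dt.timedelta(days=int(day_offset))).strftime("%Y%m%d")


def generate_cohort(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Write a synthetic file set and return its manifest.

    The manifest holds per-file row counts, ground-truth stratum/target
    counts and the injected signal list; it is also written to
    ``manifest.json`` alongside ``ground_truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    pts = sorted(config.baseline_pt_probs)
    base_p = np.array([config.baseline_pt_probs[pt] for pt in pts])

    # --- demographics ------------------------------------------------------
    is_target = rng.random(n) < config.frac_target_drug
    is_child = rng.random(n) < config.frac_children
    age_missing = rng.random(n) < config.frac_missing_age
    raw_age_years = np.where(
        is_child, rng.uniform(0.25, 17.5, n), rng.uniform(18.0, 90.0, n)
    )
    unit_pick = rng.random(n)
    sexes = rng.choice(len(_SEXES), size=n, p=_SEX_P)
    weight_missing = rng.random(n) < 0.77
    weights = np.where(
        is_child,
        np.clip(rng.normal(30, 15, n), 3, 90),
        np.clip(rng.normal(75, 20, n), 35, 160),
    )
    countries = rng.choice(len(_COUNTRIES), size=n, p=_COUNTRY_P)
    occupations = rng.choice(len(_OCCUPATIONS), size=n, p=_OCCUPATION_P)

    # therapy start, onset interval, FDA receipt date
    start_offset = rng.integers(0, _SPAN_DAYS - 800, size=n)
    tto = config.tto_distribution
    onset_days = np.round(
        rng.lognormal(np.log(tto.median_days), tto.sigma, size=n)
    ).astype(int)
    report_delay = rng.integers(0, 180, size=n)
    start_missing = rng.random(n) < config.frac_missing_start_date
    start_partial = rng.random(n) < config.frac_partial_start_date

    dup_mask = rng.random(n) < config.frac_duplicates
    dup_branch_toggle = rng.random(n) < 0.5  # True: earlier FDA_DT; False: same date
    dup_backdate = rng.integers(30, 400, size=n)

    # --- per-case age tokens & ground-truth strata -------------------------
    ages: List[Optional[float]] = []
    units: List[Optional[str]] = []
    strata: List[str] = []
    for i in range(n):
        if age_missing[i]:
            ages.append(None)
            units.append(None)
            strata.append("excluded")
            continue
        yrs = raw_age_years[i]
        u = unit_pick[i]
        if yrs < 2.0 and u < 0.5:
            value, unit = round(yrs * 12), "MON"
        elif u < 0.05:
            value, unit = round(yrs / 10, 1), "DEC"
        elif u < 0.10:
            value, unit = None, None  # unit missing, value in years
            value = round(yrs, 1)
        else:
            value, unit = round(yrs, 1), "YR"
        ages.append(float(value))
        units.append(unit)
        # stratum from the *emitted* token so rounding cannot flip it
        strata.append(assign_stratum(normalize_age(float(value), unit)))

    # --- reactions: baseline x injected risk ratio -------------------------
    prob = np.tile(base_p, (n, 1))
    for sig in config.injected_signals:
        j = pts.index(sig.pt)
        hit = is_target.copy()
        if sig.stratum != "both":
            hit &= np.array([s == sig.stratum for s in strata])
        prob[hit, j] = np.clip(prob[hit, j] * sig.risk_ratio, 0.0, 0.97)
    react_draw = rng.random((n, len(pts))) < prob
    # every report needs at least one reaction
    empty_rows = ~react_draw.any(axis=1)
    if empty_rows.any():
        fallback = rng.choice(len(pts), size=int(empty_rows.sum()), p=base_p / base_p.sum())
        for row, j in zip(np.flatnonzero(empty_rows), fallback):
            react_draw[row, j] = True

    # --- assemble records --------------------------------------------------
    demo: List[fio.DemographicRecord] = []
    drug: List[fio.DrugRecord] = []
    reac: List[fio.ReactionRecord] = []
    indi: List[fio.IndicationRecord] = []
    ther: List[fio.TherapyRecord] = []
    rpsr: List[fio.ReportSourceRecord] = []
    n_dup_rows = 0

    other_drugs = [f"DRUG {i:02d}" for i in range(1, config.n_other_drugs + 1)]
    hem_pick = rng.integers(0, len(HEM_MALIGNANCY_TERMS), size=n)
    other_ind_pick = rng.integers(0, len(OTHER_INDICATION_TERMS), size=n)
    hem_indication = rng.random(n) < config.frac_hem_indication
    target_name_pick = rng.random(n) < 0.8  # VORICONAZOLE vs VFEND
    ps_drug_pick = rng.integers(0, config.n_other_drugs, size=n)
    n_concomitant = rng.integers(0, 3, size=n)
    source_pick = rng.random(n)

    for i in range(n):
        case_id = f"{i + 1:08d}"
        pid = f"{case_id}2"  # retained version
        start_ok = not start_missing[i]
        event_day = int(start_offset[i]) + int(onset_days[i])
        fda_day = event_day + int(report_delay[i])
        fda_tok = _date_token(fda_day)
        event_tok = _date_token(event_day)
        if start_ok:
            start_tok = _date_token(int(start_offset[i]))
            if start_partial[i]:
                start_tok = start_tok[:6]  # month precision -> "inaccurate"
        else:
            start_tok = None

        demo.append(fio.DemographicRecord(
            primary_id=pid, case_id=case_id, fda_dt=fda_tok, event_dt=event_tok,
            age=ages[i], age_unit=units[i], sex=_SEXES[sexes[i]],
            weight_kg=None if weight_missing[i] else round(float(weights[i]), 1),
            reporter_country=_COUNTRIES[countries[i]],
            occupation=_OCCUPATIONS[occupations[i]],
        ))
        if is_target[i]:
            ps_name = TARGET_DRUG_NAMES[0] if target_name_pick[i] else TARGET_DRUG_NAMES[1]
        else:
            ps_name = other_drugs[ps_drug_pick[i]]
        drug.append(fio.DrugRecord(primary_id=pid, drug_name=ps_name, role="PS"))
        for k in range(int(n_concomitant[i])):
            conc = other_drugs[(ps_drug_pick[i] + k + 1) % len(other_drugs)]
            drug.append(fio.DrugRecord(primary_id=pid, drug_name=conc, role="C"))
        case_pts = [pts[j] for j in np.flatnonzero(react_draw[i])]
        for pt in case_pts:
            reac.append(fio.ReactionRecord(primary_id=pid, pt=pt))
        ind = (HEM_MALIGNANCY_TERMS[hem_pick[i]] if hem_indication[i]
               else OTHER_INDICATION_TERMS[other_ind_pick[i]])
        indi.append(fio.IndicationRecord(primary_id=pid, indication_pt=ind))
        ther.append(fio.TherapyRecord(primary_id=pid, start_dt=start_tok,
                                      end_dt=None))
        rpsr.append(fio.ReportSourceRecord(
            primary_id=pid, source_code="HP" if source_pick[i] < 0.9 else "CSM"))

        if dup_mask[i]:
            # superseded version: either an earlier FDA_DT (clause 1 of the
            # dedup rule) or the same FDA_DT with a lower PRIMARYID (clause 2)
            n_dup_rows += 1
            dup_pid = f"{case_id}1"
            dup_fda = (_date_token(max(fda_day - int(dup_backdate[i]), 0))
                       if dup_branch_toggle[i] else fda_tok)
            demo.append(fio.DemographicRecord(
                primary_id=dup_pid, case_id=case_id, fda_dt=dup_fda,
                event_dt=event_tok, age=ages[i], age_unit=units[i],
                sex=_SEXES[sexes[i]], weight_kg=None,
                reporter_country=_COUNTRIES[countries[i]],
                occupation=_OCCUPATIONS[occupations[i]],
            ))
            drug.append(fio.DrugRecord(primary_id=dup_pid, drug_name=ps_name, role="PS"))
            if case_pts:
                reac.append(fio.ReactionRecord(primary_id=dup_pid, pt=case_pts[0]))
            indi.append(fio.IndicationRecord(primary_id=dup_pid, indication_pt=ind))

    files = {}
    for kind, records in (("DEMO", demo), ("DRUG", drug), ("REAC", reac),
                          ("INDI", indi), ("THER", ther), ("RPSR", rpsr)):
        path = out / fio.FILE_NAMES[kind]
        files[kind] = {"path": path.name, "rows": fio.write_table(records, path, kind)}

    gt_path = out / "ground_truth.csv"
    with gt_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("pt,stratum,risk_ratio\n")
        for sig in config.injected_signals:
            fh.write(f"{sig.pt},{sig.stratum},{sig.risk_ratio}\n")

    manifest = {
        "n_cases": n,
        "n_duplicate_rows": n_dup_rows,
        "n_target": int(is_target.sum()),
        "n_hem_indication": int(hem_indication.sum()),
        "stratum_counts": {
            s: int(sum(x == s for x in strata)) for s in ("child", "adult", "excluded")
        },
        "target_stratum_counts": {
            s: int(sum(is_target[i] and strata[i] == s for i in range(n)))
            for s in ("child", "adult", "excluded")
        },
        "files": files,
        "injected_signals": [s.model_dump() for s in config.injected_signals],
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
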