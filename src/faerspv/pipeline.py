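"""Pipeline orchestration: config validation and the run-all driver.

A single structured config file (YAML) drives ingest -> preprocess ->
screen -> stratified comparison -> time-to-onset.  Every stage writes CSV
outputs plus a JSON run manifest with the row counts at each stage, so
the exclusion accounting is auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__
from . import io as fio
from .dictionary import MiniDictionary
from .preprocess import ADULT, CHILD, build_cohort
from .signal_stats import SignalCriteria, format_signal_table, screen
from .stratified import annual_counts, demographics_table, soc_shares, volcano_rows
from .synthetic import HEM_MALIGNANCY_TERMS, TARGET_DRUG_NAMES
from .time_to_onset import compute_tto, summarize_tto

logger = logging.getLogger(__name__)


class CriteriaConfig(BaseModel):
    min_count: int = Field(default=3, gt=0)
    ror_lo_gt: float = Field(default=1.0, gt=0)
    prr_ge: float = Field(default=2.0, gt=0)
    chi2_ge: float = Field(default=4.0, gt=0)
    ic025_gt: float = 0.0
    ebgm05_gt: float = Field(default=2.0, gt=0)

    def to_criteria(self) -> SignalCriteria:
        return SignalCriteria(**self.model_dump())


class RunConfig(BaseModel):
    input_dir: Path
    dictionary_file: Path
    output_dir: Path
    drug_names: List[str] = list(TARGET_DRUG_NAMES)
    role: str = "PS"
    indication_terms_file: Optional[Path] = None
    indication_terms: List[str] = list(HEM_MALIGNANCY_TERMS)
    age_cutoff_years: float = Field(default=18.0, gt=0)
    criteria: CriteriaConfig = Field(default_factory=CriteriaConfig)
    ic_variant: str = "bate"
    yates: bool = False
    haldane: bool = False
    eb_mode: str = "simple"
    q_threshold: float = Field(default=0.05, gt=0, le=1)
    tto_bin_edges: List[int] = [30, 60, 90, 180, 360]
    seed: int = 0

    @field_validator("ic_variant")
    @classmethod
    def _known_ic(cls, v):
        if v not in ("bate", "count"):
            raise ValueError("ic_variant must be 'bate' or 'count'")
        return v

    @field_validator("eb_mode")
    @classmethod
    def _known_eb(cls, v):
        if v not in ("simple", "full"):
            raise ValueError("eb_mode must be 'simple' or 'full'")
        return v

    @field_validator("tto_bin_edges")
    @classmethod
    def _increasing(cls, v):
        if sorted(v) != v or len(set(v)) != len(v) or (v and v[0] <= 0):
            raise ValueError("tto_bin_edges must be strictly increasing positives")
        return v


class ConfigError(ValueError):
    """Invalid run config; carries every accumulated error message."""

    def __init__(self, errors: List[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, accumulating all errors."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        raise ConfigError(msgs) from exc
    errors = []
    if not cfg.input_dir.is_dir():
        errors.append(f"input_dir: {cfg.input_dir} is not a directory")
    if not cfg.dictionary_file.is_file():
        errors.append(f"dictionary_file: {cfg.dictionary_file} not found")
    if cfg.indication_terms_file is not None:
        if not cfg.indication_terms_file.is_file():
            errors.append(
                f"indication_terms_file: {cfg.indication_terms_file} not found"
            )
    if errors:
        raise ConfigError(errors)
    return cfg


def _load_indication_terms(cfg: RunConfig) -> List[str]:
    if cfg.indication_terms_file is not None:
        lines = cfg.indication_terms_file.read_text(encoding="utf-8").splitlines()
        terms = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
        if not terms:
            raise ConfigError(["indication_terms_file: no terms found"])
        return terms
    return cfg.indication_terms


def load_tables(input_dir: Path) -> Tuple[list, list, list, list, list]:
    d = Path(input_dir)
    return (
        list(fio.read_table(d / fio.FILE_NAMES["DEMO"], "DEMO")),
        list(fio.read_table(d / fio.FILE_NAMES["DRUG"], "DRUG")),
        list(fio.read_table(d / fio.FILE_NAMES["REAC"], "REAC")),
        list(fio.read_table(d / fio.FILE_NAMES["INDI"], "INDI")),
        list(fio.read_table(d / fio.FILE_NAMES["THER"], "THER")),
    )


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = MiniDictionary.load(cfg.dictionary_file)
    terms = _load_indication_terms(cfg)

    demo, drug, reac, indi, ther = load_tables(cfg.input_dir)
    universe, cohort, audit = build_cohort(
        demo, drug, reac, indi, ther,
        drug_names=set(cfg.drug_names), indication_terms=set(terms),
        role=cfg.role, age_cutoff=cfg.age_cutoff_years,
    )
    logger.info("cohort audit: %s", audit.as_dict())

    criteria = cfg.criteria.to_criteria()
    screens = {}
    for level in ("SOC", "PT"):
        for stratum in (CHILD, ADULT):
            df = screen(
                universe, level=level, stratum=stratum, dictionary=dictionary,
                criteria=criteria, ic_variant=cfg.ic_variant, yates=cfg.yates,
                haldane=cfg.haldane, eb_mode=cfg.eb_mode,
            )
            screens[(level, stratum)] = df
            stem = f"signals_{level.lower()}_{stratum}"
            df.to_csv(out / f"{stem}.csv", index=False)
            format_signal_table(df).to_csv(out / f"{stem}_formatted.csv", index=False)

    volcano = volcano_rows(
        screens[("PT", CHILD)], screens[("PT", ADULT)], q_threshold=cfg.q_threshold
    )
    volcano.to_csv(out / "volcano.csv", index=False)
    shares = soc_shares(screens[("SOC", CHILD)], screens[("SOC", ADULT)])
    shares.to_csv(out / "soc_shares.csv", index=False)
    demographics_table(cohort).to_csv(out / "demographics.csv", index=False)
    annual_counts(cohort).to_csv(out / "annual_counts.csv", index=False)

    records, tto_audit = compute_tto(cohort, edges=cfg.tto_bin_edges)
    summarize_tto(records, edges=cfg.tto_bin_edges).to_csv(
        out / "tto_summary.csv", index=False
    )
    with (out / "tto_exclusions.csv").open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("reason,count\n")
        for reason, count in tto_audit.items():
            fh.write(f"{reason},{count}\n")

    manifest = {
        "version": __version__,
        "stages": {
            **audit.as_dict(),
            "n_tto_included": tto_audit["included"],
            "n_positive": {
                f"{lvl}/{st}": int(screens[(lvl, st)]["positive"].sum())
                for (lvl, st) in screens
            },
        },
        "variants": {
            "ic_variant": cfg.ic_variant, "yates": cfg.yates,
            "haldane": cfg.haldane, "eb_mode": cfg.eb_mode,
            "raw_test": "fisher-exact",
        },
        "config": json.loads(cfg.model_dump_json()),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
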