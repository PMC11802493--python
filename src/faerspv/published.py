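"""Published summary counts and SOC-level signal rows for voriconazole in
hematological-malignancy patients (FAERS 2004Q1-2024Q1).

These are the printed inputs the consistency checks run on: demographic
counts, time-to-onset bin counts, and the SOC-level statistics tables for
the child and adult strata.  Only printed numbers appear here; nothing is
derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

TOTAL_CASES = 605
CHILD_CASES = 116
ADULT_CASES = 489
MALE_CASES = 372
FEMALE_CASES = 214

#: reporter-type counts (child, adult) for the professional categories
PROFESSIONAL_COUNTS = {
    "Physician": (26, 162),
    "Pharmacist": (7, 18),
    "Health-professional": (76, 245),
}

#: time-to-onset: included records and the two printed bins
TTO_TOTAL = 81
TTO_BIN_COUNTS = {"0-30": 60, "31-60": 11}
TTO_MEDIAN_DAYS = {"child": 11.0, "adult": 8.5}


@dataclass(frozen=True)
class PublishedRow:
    """One printed SOC-level row: frequency and the four statistics."""

    term: str
    a: int
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    chi2: float
    ebgm: float
    ebgm05: float
    ic: float
    ic025: float


#: child-stratum SOC table
CHILD_SOC_ROWS: Tuple[PublishedRow, ...] = (
    PublishedRow("Psychiatric disorders", 31, 3.46, 2.4, 4.98, 3.32, 50.05, 3.27, 2.41, 1.71, 0.04),
    PublishedRow("Skin and subcutaneous tissue disorders", 47, 3.08, 2.28, 4.16, 2.91, 59.34, 2.87, 2.23, 1.52, -0.15),
    PublishedRow("General disorders and administration site conditions", 124, 2.45, 2.01, 2.99, 2.14, 82.35, 2.12, 1.79, 1.08, -0.59),
    PublishedRow("Product issues", 1, 1.98, 0.27, 14.26, 1.98, 0.48, 1.96, 0.38, 0.97, -0.73),
    PublishedRow("Ear and labyrinth disorders", 1, 1.95, 0.27, 14.06, 1.95, 0.46, 1.94, 0.37, 0.95, -0.75),
    PublishedRow("Injury, poisoning and procedural complications", 45, 1.67, 1.23, 2.26, 1.61, 10.9, 1.61, 1.24, 0.68, -0.99),
    PublishedRow("Hepatobiliary disorders", 22, 1.35, 0.88, 2.07, 1.34, 1.89, 1.33, 0.93, 0.41, -1.26),
    PublishedRow("Renal and urinary disorders", 15, 1.23, 0.74, 2.07, 1.23, 0.64, 1.23, 0.8, 0.29, -1.38),
    PublishedRow("Infections and infestations", 81, 1.12, 0.88, 1.42, 1.1, 0.89, 1.1, 0.91, 0.14, -1.53),
    PublishedRow("Musculoskeletal and connective tissue disorders", 12, 1.04, 0.59, 1.85, 1.04, 0.02, 1.04, 0.64, 0.05, -1.62),
    PublishedRow("Gastrointestinal disorders", 42, 0.87, 0.63, 1.19, 0.88, 0.81, 0.88, 0.67, -0.19, -1.86),
    PublishedRow("Cardiac disorders", 10, 0.82, 0.44, 1.54, 0.83, 0.37, 0.83, 0.49, -0.27, -1.94),
    PublishedRow("Nervous system disorders", 49, 0.75, 0.56, 1.0, 0.77, 3.76, 0.77, 0.6, -0.37, -2.05),
    PublishedRow("Investigations", 34, 0.67, 0.47, 0.95, 0.69, 5.15, 0.69, 0.52, -0.53, -2.2),
    PublishedRow("Endocrine disorders", 2, 0.66, 0.16, 2.64, 0.66, 0.35, 0.66, 0.21, -0.6, -2.27),
    PublishedRow("Respiratory, thoracic and mediastinal disorders", 13, 0.51, 0.29, 0.88, 0.52, 6.03, 0.52, 0.33, -0.94, -2.61),
    PublishedRow("Metabolism and nutrition disorders", 10, 0.48, 0.25, 0.89, 0.49, 5.63, 0.49, 0.29, -1.04, -2.71),
    PublishedRow("Blood and lymphatic system disorders", 25, 0.37, 0.25, 0.55, 0.39, 26.16, 0.4, 0.28, -1.34, -3.01),
    PublishedRow("Eye disorders", 2, 0.33, 0.08, 1.33, 0.33, 2.69, 0.33, 0.1, -1.58, -3.25),
    PublishedRow("Vascular disorders", 3, 0.2, 0.07, 0.63, 0.21, 9.37, 0.21, 0.08, -2.27, -3.94),
    PublishedRow("Immune system disorders", 3, 0.19, 0.06, 0.58, 0.19, 10.7, 0.19, 0.07, -2.39, -4.06),
    PublishedRow("Neoplasms benign, malignant and unspecified", 2, 0.1, 0.02, 0.38, 0.1, 16.99, 0.1, 0.03, -3.33, -5.0),
)

#: adult-stratum SOC table
ADULT_SOC_ROWS: Tuple[PublishedRow, ...] = (
    PublishedRow("Endocrine disorders", 18, 5.82, 3.65, 9.28, 5.78, 70.69, 5.74, 3.89, 2.52, 0.85),
    PublishedRow("Hepatobiliary disorders", 77, 3.46, 2.75, 4.35, 3.36, 128.72, 3.35, 2.77, 1.74, 0.08),
    PublishedRow("Eye disorders", 57, 2.47, 1.9, 3.21, 2.42, 48.14, 2.42, 1.94, 1.27, -0.39),
    PublishedRow("Infections and infestations", 365, 1.89, 1.68, 2.11, 1.72, 123.35, 1.72, 1.56, 0.78, -0.89),
    PublishedRow("Psychiatric disorders", 51, 1.49, 1.13, 1.97, 1.47, 7.92, 1.47, 1.17, 0.56, -1.11),
    PublishedRow("General disorders and administration site conditions", 374, 1.38, 1.23, 1.54, 1.31, 31.34, 1.31, 1.19, 0.38, -1.28),
    PublishedRow("Cardiac disorders", 72, 1.13, 0.9, 1.44, 1.13, 1.1, 1.13, 0.93, 0.18, -1.49),
    PublishedRow("Nervous system disorders", 144, 1.07, 0.9, 1.27, 1.07, 0.65, 1.07, 0.93, 0.09, -1.57),
    PublishedRow("Injury, poisoning and procedural complications", 131, 1.03, 0.87, 1.23, 1.03, 0.13, 1.03, 0.89, 0.04, -1.62),
    PublishedRow("Investigations", 179, 1.01, 0.87, 1.18, 1.01, 0.03, 1.01, 0.89, 0.02, -1.65),
    PublishedRow("Renal and urinary disorders", 35, 0.86, 0.62, 1.2, 0.86, 0.76, 0.86, 0.65, -0.21, -1.88),
    PublishedRow("Blood and lymphatic system disorders", 104, 0.81, 0.67, 0.99, 0.82, 4.25, 0.82, 0.7, -0.28, -1.95),
    PublishedRow("Respiratory, thoracic and mediastinal disorders", 84, 0.78, 0.63, 0.97, 0.79, 4.98, 0.79, 0.66, -0.34, -2.01),
    PublishedRow("Pregnancy, puerperium and perinatal conditions", 1, 0.78, 0.11, 5.57, 0.78, 0.06, 0.78, 0.15, -0.35, -2.02),
    PublishedRow("Congenital, familial and genetic disorders", 2, 0.76, 0.19, 3.04, 0.76, 0.15, 0.76, 0.24, -0.4, -2.07),
    PublishedRow("Immune system disorders", 19, 0.75, 0.48, 1.17, 0.75, 1.61, 0.75, 0.51, -0.42, -2.08),
    PublishedRow("Vascular disorders", 33, 0.69, 0.49, 0.97, 0.7, 4.5, 0.7, 0.52, -0.52, -2.19),
    PublishedRow("Reproductive system and breast disorders", 3, 0.64, 0.2, 1.97, 0.64, 0.62, 0.64, 0.25, -0.65, -2.32),
    PublishedRow("Skin and subcutaneous tissue disorders", 57, 0.63, 0.48, 0.82, 0.64, 11.91, 0.64, 0.52, -0.64, -2.31),
    PublishedRow("Metabolism and nutrition disorders", 33, 0.62, 0.44, 0.88, 0.63, 7.42, 0.63, 0.47, -0.67, -2.34),
    PublishedRow("Neoplasms benign, malignant and unspecified", 47, 0.45, 0.33, 0.6, 0.46, 31.53, 0.46, 0.36, -1.12, -2.79),
    PublishedRow("Gastrointestinal disorders", 49, 0.27, 0.21, 0.36, 0.29, 92.49, 0.29, 0.23, -1.78, -3.45),
    PublishedRow("Musculoskeletal and connective tissue disorders", 17, 0.22, 0.14, 0.36, 0.23, 45.21, 0.23, 0.16, -2.11, -3.78),
    PublishedRow("Surgical and medical procedures", 2, 0.11, 0.03, 0.45, 0.11, 14.08, 0.11, 0.04, -3.15, -4.81),
)

#: headline PT-level EBGM values whose IC must equal log2(EBGM)
IC_EBGM_PAIRS: Dict[str, Tuple[float, float]] = {
    # term -> (printed EBGM, printed IC)
    "psychiatric disorders (child SOC)": (3.27, 1.71),
    "toxic optic neuropathy (adult PT)": (580.96, 9.18),
}
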