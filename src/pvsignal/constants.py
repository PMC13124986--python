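"""Shared vocabulary: table schemas, drug synonyms, suicide PTs, code maps.

The FAERS quarterly ASCII dialect used throughout is dollar-sign-delimited
text with one header row, no quoting, dates as 8-digit YYYYMMDD integers and
missing values as empty fields.
"""

from __future__ import annotations

FAERS_DELIMITER = "$"

# Column subset of the real FAERS quarterly tables that this pipeline uses.
FAERS_SCHEMAS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "event_dt",
        "age", "age_cod", "sex", "wt", "wt_cod",
        "reporter_country", "occp_cod",
    ],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
}

FAERS_TABLES = tuple(FAERS_SCHEMAS)

#: Names under which vortioxetine appears in FAERS DRUG records.
VORTIOXETINE_SYNONYMS: tuple[str, ...] = (
    "Lu AA21004",
    "Brintellix",
    "Vortioxetine Hydrobromide",
    "Vortioxetine",
    "Vortioxetine hbr",
    "1-(2-(2,4-Dimethylphenylsulfanyl)phenyl)piperazine",
)

#: MedDRA preferred terms counted as suicide-related events.
SUICIDE_PTS: tuple[str, ...] = (
    "Suicidal ideation",
    "Suicide attempt",
    "Completed suicide",
    "Suicidal behaviour",
    "Suicide threat",
    "Depression suicidal",
    "Columbia suicide severity rating scale abnormal",
)

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

OUTCOME_CODES: dict[str, str] = {
    "CA": "Congenital anomaly",
    "DE": "Death",
    "DS": "Disability",
    "HO": "Hospitalization",
    "LT": "Life-threatening",
    "OT": "Other",
}

REPORTER_CODES: dict[str, str] = {
    "CN": "Consumer",
    "MD": "Physician",
    "OT": "Healthcare professional",
    "PH": "Pharmacist",
}

# Age unit codes and the factor converting the stated value to years.
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: Ages above this many years are treated as data errors and set missing.
MAX_PLAUSIBLE_AGE_YEARS = 120.0

LBS_PER_KG = 1.0 / 0.45359

WEIGHT_UNIT_TO_KG: dict[str, float] = {
    "KG": 1.0,
    "KGS": 1.0,
    "LBS": 0.45359,
    "IB": 0.45359,
}

SENTINEL_SOC = "UNMAPPED"
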