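"""Reading, deduplicating and assembling FAERS quarterly ASCII tables.

The FDA distributes each quarter as five dollar-delimited text tables
(DEMO, DRUG, REAC, OUTC, THER) linked by a primary ID. A case can appear in
several quarters as successive versions; the FDA-recommended cleaning rule
keeps, per Case ID, the version with the latest FDA receipt date, breaking
ties by the highest primary ID. Everything downstream (disproportionality,
time-to-onset, subgroups) operates on the deduplicated, unit-normalised
records produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ValidationError
from .constants import (
    AGE_UNIT_TO_YEARS,
    FAERS_DELIMITER,
    FAERS_SCHEMAS,
    FAERS_TABLES,
    MAX_PLAUSIBLE_AGE_YEARS,
    SENTINEL_SOC,
    WEIGHT_UNIT_TO_KG,
)
from .quarters import file_suffix

logger = logging.getLogger(__name__)


@dataclass
class IngestReport:
    """Counters accumulated while reading and assembling a bundle."""

    rows_read: dict[str, int] = field(default_factory=dict)
    malformed_dates: int = 0
    duplicates_removed: int = 0
    implausible_ages: int = 0
    orphan_reactions: int = 0
    reports_without_reactions: int = 0
    unmapped_pts: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rows_read": dict(self.rows_read),
            "malformed_dates": self.malformed_dates,
            "duplicates_removed": self.duplicates_removed,
            "implausible_ages": self.implausible_ages,
            "orphan_reactions": self.orphan_reactions,
            "reports_without_reactions": self.reports_without_reactions,
            "unmapped_pts": sorted(set(self.unmapped_pts)),
        }


def read_faers_ascii(
    directory: str | Path,
    quarters: list[str] | tuple[str, ...],
    report: IngestReport | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Read the five tables for each quarter into string DataFrames.

    Missing mandatory files raise immediately with the expected file name;
    malformed rows are never silently dropped (pandas raises on ragged rows
    in this quote-free dialect, and date parsing later only blanks fields).
    """
    directory = Path(directory)
    expected = [
        (name, q, directory / f"{name}{file_suffix(q)}.txt")
        for q in quarters
        for name in FAERS_TABLES
    ]
    missing = [str(p) for _, _, p in expected if not p.exists()]
    if missing:
        raise FileNotFoundError(
            "missing FAERS table file(s): " + ", ".join(missing)
        )
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for name, q, path in expected:
        frame = pd.read_csv(
            path, sep=FAERS_DELIMITER, dtype=str, keep_default_na=False,
            engine="python",
        )
        want = FAERS_SCHEMAS[name]
        if list(frame.columns) != want:
            raise ValidationError(
                f"{path.name}: header {list(frame.columns)} != expected {want}"
            )
        tables[(name, q)] = frame
        if report is not None:
            report.rows_read[name] = report.rows_read.get(name, 0) + len(frame)
    return tables


def concat_quarters(
    tables: dict[tuple[str, str], pd.DataFrame], name: str
) -> pd.DataFrame:
    frames = [frame for (n, _), frame in sorted(tables.items()) if n == name]
    if not frames:
        return pd.DataFrame(columns=FAERS_SCHEMAS[name])
    return pd.concat(frames, ignore_index=True)


def _stringify(frame: pd.DataFrame) -> pd.DataFrame:
    """Normalise a table to string cells with '' as missing, so in-memory
    simulated tables and disk round-trips behave identically."""
    return frame.astype(str).replace({"nan": "", "<NA>": "", "None": ""})


def _parse_dates(col: pd.Series, report: IngestReport | None = None) -> pd.Series:
    """YYYYMMDD strings -> Timestamps; malformed values become NaT with a
    warning (the row itself is retained)."""
    col = col.astype(str)
    out = pd.to_datetime(col.str.strip(), format="%Y%m%d", errors="coerce")
    bad = out.isna() & (col.str.strip() != "")
    nbad = int(bad.sum())
    if nbad:
        logger.warning("%d unparseable date(s) set to missing", nbad)
        if report is not None:
            report.malformed_dates += nbad
    return out


def deduplicate(demo: pd.DataFrame, report: IngestReport | None = None) -> pd.DataFrame:
    """Keep one version per case: latest FDA date, ties to highest primary ID.

    Output is sorted by case ID; idempotent; never invents rows.
    """
    if demo.empty:
        return demo.copy()
    work = demo.copy()
    work["_pid"] = pd.to_numeric(work["primaryid"])
    work["_cid"] = pd.to_numeric(work["caseid"])
    work["_fda"] = pd.to_numeric(work["fda_dt"].astype(str).str.strip(),
                                 errors="coerce").fillna(-1)
    work = work.sort_values(["_cid", "_fda", "_pid"], kind="mergesort")
    kept = work.groupby("_cid", sort=True).tail(1)
    if report is not None:
        report.duplicates_removed += len(demo) - len(kept)
    return kept.drop(columns=["_pid", "_cid", "_fda"]).reset_index(drop=True)


def normalize_name(name: str) -> str:
    """Case-fold, trim, and collapse internal whitespace."""
    return " ".join(str(name).split()).casefold()


def select_target_reports(
    drug: pd.DataFrame,
    synonyms: list[str] | tuple[str, ...],
    roles: frozenset[str] | set[str] = frozenset({"PS"}),
) -> set[str]:
    """Primary IDs with >=1 drug entry matching a synonym in a given role.

    Matching is exact after normalisation (never substring), so combination
    products or lookalike names are not captured accidentally.
    """
    if not synonyms:
        raise ValidationError("synonym list must be non-empty")
    wanted = {normalize_name(s) for s in synonyms}
    mask = (
        drug["drugname"].map(normalize_name).isin(wanted)
        & drug["role_cod"].str.strip().isin(roles)
    )
    return set(drug.loc[mask, "primaryid"].astype(str))


def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (PT <tab> SOC) -> case-normalised mapping."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"malformed PT->SOC line: {line!r}")
        mapping[normalize_name(parts[0])] = parts[1].strip()
    return mapping


def map_pt_to_soc(pt: str, pt_soc_map: dict[str, str]) -> str:
    return pt_soc_map.get(normalize_name(pt), SENTINEL_SOC)


def convert_age_years(value: str, unit: str) -> float:
    """FAERS age value + unit code -> years (NaN if missing/implausible)."""
    value = str(value).strip()
    if not value:
        return np.nan
    try:
        v = float(value)
    except ValueError:
        return np.nan
    factor = AGE_UNIT_TO_YEARS.get(str(unit).strip().upper())
    if factor is None:
        factor = 1.0 if not str(unit).strip() else np.nan
    years = v * factor
    if not np.isfinite(years) or years < 0 or years > MAX_PLAUSIBLE_AGE_YEARS:
        return np.nan
    return years


def convert_weight_kg(value: str, unit: str) -> float:
    value = str(value).strip()
    if not value:
        return np.nan
    try:
        v = float(value)
    except ValueError:
        return np.nan
    factor = WEIGHT_UNIT_TO_KG.get(str(unit).strip().upper())
    if factor is None:
        factor = 1.0 if not str(unit).strip() else np.nan
    kg = v * factor
    if not np.isfinite(kg) or kg <= 0:
        return np.nan
    return kg


@dataclass
class Cohort:
    """Deduplicated, unit-normalised analysis set.

    ``records`` has one row per surviving report (all drugs); ``target_ids``
    marks the reports where the drug of interest is primary suspect.
    ``reactions`` is long-format unique (report, PT); ``therapy_starts`` the
    earliest target-drug therapy start per report.
    """

    records: pd.DataFrame
    reactions: pd.DataFrame
    drugs: pd.DataFrame
    outcomes: pd.DataFrame
    therapy_starts: pd.Series
    target_ids: set[str]
    report: IngestReport

    @property
    def n_reports(self) -> int:
        return len(self.records)

    @property
    def n_target(self) -> int:
        return len(self.target_ids)


def assemble_records(
    tables: dict[tuple[str, str], pd.DataFrame],
    synonyms: list[str] | tuple[str, ...],
    report: IngestReport | None = None,
) -> Cohort:
    """Deduplicate DEMO and join DRUG/REAC/OUTC/THER to surviving reports."""
    report = report if report is not None else IngestReport()
    tables = {key: _stringify(frame) for key, frame in tables.items()}

    demo = deduplicate(concat_quarters(tables, "DEMO"), report)
    keep = set(demo["primaryid"].astype(str))

    drug = concat_quarters(tables, "DRUG")
    drug = drug[drug["primaryid"].astype(str).isin(keep)].reset_index(drop=True)

    reac = concat_quarters(tables, "REAC")
    n_before = len(reac)
    reac = reac[reac["primaryid"].astype(str).isin(keep)]
    report.orphan_reactions += n_before - len(reac)
    # one count per unique (report, PT): a PT repeated inside a report is one event
    reac = reac.assign(pt_norm=reac["pt"].map(normalize_name))
    reac = reac.drop_duplicates(["primaryid", "pt_norm"]).reset_index(drop=True)

    outc = concat_quarters(tables, "OUTC")
    outc = outc[outc["primaryid"].astype(str).isin(keep)].reset_index(drop=True)

    target_ids = select_target_reports(drug, synonyms)

    records = demo.copy()
    records["primaryid"] = records["primaryid"].astype(str)
    records["caseid"] = records["caseid"].astype(str)
    records["fda_date"] = _parse_dates(records.pop("fda_dt"), report)
    records["event_date"] = _parse_dates(records.pop("event_dt"), report)
    records["sex"] = records.pop("sex").str.strip().str.upper().replace(
        {"F": "Female", "M": "Male", "": "Missing", "UNK": "Missing"}
    )
    ages = [
        convert_age_years(v, u)
        for v, u in zip(records["age"], records["age_cod"])
    ]
    n_stated = int((records["age"].str.strip() != "").sum())
    records["age_years"] = ages
    report.implausible_ages += n_stated - int(np.isfinite(ages).sum())
    records["weight_kg"] = [
        convert_weight_kg(v, u)
        for v, u in zip(records["wt"], records["wt_cod"])
    ]
    records["country"] = records.pop("reporter_country").str.strip()
    records["reporter"] = records.pop("occp_cod").str.strip().str.upper()
    records = records.drop(columns=["age", "age_cod", "wt", "wt_cod"])

    # earliest target-drug therapy start per report
    ther = concat_quarters(tables, "THER")
    ther = ther[ther["primaryid"].astype(str).isin(keep)].copy()
    target_seqs = drug.loc[
        drug["primaryid"].astype(str).isin(target_ids)
        & drug["drugname"].map(normalize_name).isin(
            {normalize_name(s) for s in synonyms}
        ),
        ["primaryid", "drug_seq"],
    ].astype(str)
    ther = ther.astype({"primaryid": str, "dsg_drug_seq": str})
    ther = ther.merge(
        target_seqs, left_on=["primaryid", "dsg_drug_seq"],
        right_on=["primaryid", "drug_seq"],
    )
    ther["start_date"] = _parse_dates(ther["start_dt"], report)
    therapy_starts = ther.groupby("primaryid")["start_date"].min()

    reac["primaryid"] = reac["primaryid"].astype(str)
    with_reac = set(reac["primaryid"])
    n_empty = sum(1 for pid in records["primaryid"] if pid not in with_reac)
    if n_empty:
        logger.info("%d report(s) carry zero reactions (retained)", n_empty)
    report.reports_without_reactions += n_empty

    return Cohort(
        records=records.sort_values("caseid", kind="mergesort").reset_index(drop=True),
        reactions=reac[["primaryid", "caseid", "pt", "pt_norm"]],
        drugs=drug,
        outcomes=outc,
        therapy_starts=therapy_starts,
        target_ids=target_ids,
        report=report,
    )
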