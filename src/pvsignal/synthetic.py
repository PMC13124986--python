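"""Synthetic FAERS-style quarterly tables with known ground truth.

The generator emulates a spontaneous-reporting population: each report has
one primary-suspect drug, a set of MedDRA-like preferred terms drawn with
per-drug relative reporting rates, demographics with realistic missingness,
Weibull-distributed therapy-to-event onset lags, and a configurable fraction
of cases submitted in multiple versions (same Case ID, later FDA dates) to
exercise the deduplication rule. Every quantity the downstream stages must
recover is recorded in a :class:`GroundTruth` sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, ValidationError
from .constants import (
    FAERS_DELIMITER,
    FAERS_SCHEMAS,
    SUICIDE_PTS,
    VORTIOXETINE_SYNONYMS,
)
from .quarters import file_suffix, quarter_bounds

# ---------------------------------------------------------------------------
# Miniature PT -> SOC dictionary (MedDRA itself is licensed and not bundled).
# 30 named PTs in 5 SOCs; the seven suicide-related PTs sit under
# psychiatric disorders as they do in the real hierarchy.

BUILTIN_PT_SOC: dict[str, str] = {
    # Psychiatric disorders (includes the suicide-related PTs)
    "Suicidal ideation": "Psychiatric disorders",
    "Suicide attempt": "Psychiatric disorders",
    "Completed suicide": "Psychiatric disorders",
    "Suicidal behaviour": "Psychiatric disorders",
    "Suicide threat": "Psychiatric disorders",
    "Depression suicidal": "Psychiatric disorders",
    "Columbia suicide severity rating scale abnormal": "Psychiatric disorders",
    "Anxiety": "Psychiatric disorders",
    "Insomnia": "Psychiatric disorders",
    "Irritability": "Psychiatric disorders",
    "Depression": "Psychiatric disorders",
    "Agitation": "Psychiatric disorders",
    # Gastrointestinal disorders
    "Nausea": "Gastrointestinal disorders",
    "Vomiting": "Gastrointestinal disorders",
    "Constipation": "Gastrointestinal disorders",
    "Diarrhoea": "Gastrointestinal disorders",
    "Abdominal pain": "Gastrointestinal disorders",
    "Dyspepsia": "Gastrointestinal disorders",
    # Nervous system disorders
    "Headache": "Nervous system disorders",
    "Dizziness": "Nervous system disorders",
    "Somnolence": "Nervous system disorders",
    "Tremor": "Nervous system disorders",
    "Disturbance in attention": "Nervous system disorders",
    "Hypersomnia": "Nervous system disorders",
    # General disorders and administration site conditions
    "Fatigue": "General disorders and administration site conditions",
    "Asthenia": "General disorders and administration site conditions",
    "Feeling abnormal": "General disorders and administration site conditions",
    "Malaise": "General disorders and administration site conditions",
    # Skin and subcutaneous tissue disorders
    "Pruritus": "Skin and subcutaneous tissue disorders",
    "Hyperhidrosis": "Skin and subcutaneous tissue disorders",
}

_SOC_CYCLE = (
    "Psychiatric disorders",
    "Gastrointestinal disorders",
    "Nervous system disorders",
    "General disorders and administration site conditions",
    "Skin and subcutaneous tissue disorders",
)

#: Index of the simulated target drug (its DRUG rows carry the synonym names).
TARGET_DRUG = 0


def build_pt_dictionary(n_events: int) -> tuple[list[str], dict[str, str]]:
    """Event names and their SOC map for *n_events* events.

    The first 30 events use the builtin dictionary; extras get synthetic
    names cycled through the five SOCs so every PT is always mappable.
    """
    names = list(BUILTIN_PT_SOC)
    soc_map = dict(BUILTIN_PT_SOC)
    for i in range(len(names), n_events):
        name = f"Synthetic event {i:04d}"
        names.append(name)
        soc_map[name] = _SOC_CYCLE[i % len(_SOC_CYCLE)]
    return names[:n_events], {pt: soc_map[pt] for pt in names[:n_events]}


@dataclass
class GroundTruth:
    """Bookkeeping the simulator keeps so downstream stages can be checked."""

    true_rr: dict[tuple[int, int], float]
    true_onset_shape: float
    true_onset_scale_days: float
    duplicate_map: dict[int, list[int]]         # caseid -> emitted primaryids
    canonical_version: dict[int, int]           # caseid -> primaryid to keep
    drug_names: list[str]                       # index -> canonical name
    event_names: list[str]                      # index -> PT
    pt_soc_map: dict[str, str]
    report_drug: dict[int, int]                 # caseid -> suspect drug index
    report_events: dict[int, list[int]]         # caseid -> event indices
    onset_lag_days: dict[int, int]              # caseid -> whole-day lag
    target_case_ids: list[int] = field(default_factory=list)

    @property
    def n_extra_versions(self) -> int:
        return sum(len(v) - 1 for v in self.duplicate_map.values())

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["true_rr"] = {f"{k[0]},{k[1]}": v for k, v in self.true_rr.items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["true_rr"] = {
            tuple(int(x) for x in k.split(",")): v for k, v in d["true_rr"].items()
        }
        for key in ("duplicate_map", "canonical_version", "report_drug",
                    "report_events", "onset_lag_days"):
            d[key] = {int(k): v for k, v in d[key].items()}
        return cls(**d)


def _date_to_int(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] array -> YYYYMMDD ints."""
    ymd = dates.astype("datetime64[D]")
    y = ymd.astype("datetime64[Y]").astype(int) + 1970
    m = ymd.astype("datetime64[M]").astype(int) % 12 + 1
    d = (ymd - ymd.astype("datetime64[M]")).astype(int) + 1
    return y * 10000 + m * 100 + d


def _choice(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    keys = np.array(list(dist), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    return rng.choice(keys, size=n, p=probs / probs.sum())


def simulate_reports(
    config: SimulationConfig,
) -> tuple[dict[tuple[str, str], pd.DataFrame], GroundTruth]:
    """Generate the five FAERS tables per quarter plus ground truth.

    Returns a dict keyed by ``(table_name, quarter_label)`` and the
    :class:`GroundTruth` sidecar. Deterministic for a fixed config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    spec = config.demographic_spec

    event_names, pt_soc_map = build_pt_dictionary(config.n_events)
    drug_names = ["VORTIOXETINE"] + [f"DRUG {i:02d}" for i in range(1, config.n_drugs)]

    case_ids = 10_000_001 + np.arange(n)
    drug_idx = rng.integers(0, config.n_drugs, size=n)

    # Event occurrence: independent per event, probability proportional to the
    # baseline rate scaled by the planted relative reporting rate for the
    # report's suspect drug. mean_events_per_report sets the overall density.
    base = config.event_probs() * config.mean_events_per_report
    prob = np.tile(base, (n, 1))
    for (drug, event), rr in config.planted_rr.items():
        prob[drug_idx == drug, event] = base[event] * rr
    np.clip(prob, 0.0, 0.95, out=prob)
    occur = rng.random((n, config.n_events)) < prob

    # Demographics, shared across all versions of a case.
    sex = _choice(rng, dict(spec.p_sex), n)
    age_years = np.clip(rng.normal(spec.age_mean_years, spec.age_sd_years, n), 1.0, 100.0)
    age_missing = rng.random(n) < spec.p_age_missing
    wt_kg = np.clip(rng.normal(spec.weight_mean_kg, spec.weight_sd_kg, n), 35.0, 180.0)
    wt_missing = rng.random(n) < spec.p_weight_missing
    reporter = _choice(rng, dict(spec.p_reporter), n)
    outcome = _choice(rng, dict(spec.p_outcome), n)
    country = rng.choice(
        np.array(["US", "JP", "FR", "CA", "GB"], dtype=object),
        size=n, p=[0.77, 0.08, 0.06, 0.05, 0.04],
    )

    # A minority of ages/weights use non-default units to exercise conversion.
    age_unit = np.where(rng.random(n) < 0.03, "MON", "YR").astype(object)
    age_unit[rng.random(n) < 0.02] = "DEC"
    wt_unit = np.where(rng.random(n) < 0.05, "LBS", "KG").astype(object)

    # Dates: therapy start inside the report's quarter, event = start + lag,
    # FDA receipt shortly after the event.
    q_assign = rng.integers(0, len(config.quarters), size=n)
    lag_days = np.maximum(
        np.round(config.onset_scale_days
                 * rng.weibull(config.onset_shape, size=n)).astype(int),
        0,
    )
    q_starts = np.array(
        [np.datetime64(quarter_bounds(q)[0]) for q in config.quarters]
    )
    start_dt = (q_starts[q_assign]
                + rng.integers(0, 80, size=n).astype("timedelta64[D]"))
    event_dt = start_dt + lag_days.astype("timedelta64[D]")
    fda_dt = event_dt + rng.integers(1, 45, size=n).astype("timedelta64[D]")

    # Duplicate injection: a duplicate_rate fraction of cases is re-emitted in
    # 2-3 versions with strictly increasing FDA dates (occasionally an equal
    # date, so the highest-Primary-ID tie-break is exercised too).
    n_dup = int(round(config.duplicate_rate * n))
    dup_cases = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    extra_counts = rng.integers(1, 3, size=n_dup)  # 1 or 2 extra versions

    duplicate_map: dict[int, list[int]] = {}
    canonical: dict[int, int] = {}
    rows_idx: list[int] = []          # source report row per emitted version
    rows_pid: list[int] = []
    rows_fda: list[np.datetime64] = []

    version_of = np.ones(n, dtype=int)
    for i in range(n):
        pid = int(case_ids[i]) * 10 + 1
        duplicate_map[int(case_ids[i])] = [pid]
        rows_idx.append(i)
        rows_pid.append(pid)
        rows_fda.append(fda_dt[i])
        canonical[int(case_ids[i])] = pid
    for j, i in enumerate(dup_cases):
        cid = int(case_ids[i])
        last_fda = fda_dt[i]
        for v in range(int(extra_counts[j])):
            version_of[i] += 1
            pid = cid * 10 + int(version_of[i])
            if rng.random() < 0.15:
                new_fda = last_fda                  # tie: decided by primaryid
            else:
                new_fda = last_fda + np.timedelta64(int(rng.integers(1, 180)), "D")
            duplicate_map[cid].append(pid)
            rows_idx.append(int(i))
            rows_pid.append(pid)
            rows_fda.append(new_fda)
            last_fda = new_fda
    # canonical version maximises (fda_dt, primaryid)
    best: dict[int, tuple] = {}
    for i, pid, f in zip(rows_idx, rows_pid, rows_fda):
        cid = int(case_ids[i])
        key = (f.astype("datetime64[D]").astype(int), pid)
        if cid not in best or key > best[cid]:
            best[cid] = key
            canonical[cid] = pid

    src = np.array(rows_idx, dtype=int)
    pids = np.array(rows_pid, dtype=int)
    fda_all = np.array(rows_fda, dtype="datetime64[D]")

    # --- assemble long-format tables over all emitted versions -------------
    demo = pd.DataFrame({
        "primaryid": pids,
        "caseid": case_ids[src],
        "fda_dt": _date_to_int(fda_all),
        "event_dt": _date_to_int(event_dt[src].astype("datetime64[D]")),
        "age": np.where(
            age_missing[src], "",
            np.select(
                [age_unit[src] == "MON", age_unit[src] == "DEC"],
                [np.char.mod("%d", np.round(age_years[src] * 12).astype(int)),
                 np.char.mod("%.1f", age_years[src] / 10)],
                np.char.mod("%d", np.round(age_years[src]).astype(int)),
            ),
        ),
        "age_cod": np.where(age_missing[src], "", age_unit[src]),
        "sex": sex[src],
        "wt": np.where(
            wt_missing[src], "",
            np.where(wt_unit[src] == "LBS",
                     np.char.mod("%.1f", wt_kg[src] / 0.45359),
                     np.char.mod("%.1f", wt_kg[src])),
        ),
        "wt_cod": np.where(wt_missing[src], "", wt_unit[src]),
        "reporter_country": country[src],
        "occp_cod": reporter[src],
    })

    # DRUG: the PS row (target rows cycle through the synonym list with case
    # and whitespace jitter) plus one concomitant row per report.
    syn_cycle = np.array(
        [VORTIOXETINE_SYNONYMS[i % len(VORTIOXETINE_SYNONYMS)] for i in range(n)],
        dtype=object,
    )
    jitter = rng.integers(0, 3, size=n)
    syn_cycle = np.where(jitter == 1, np.char.upper(syn_cycle.astype(str)), syn_cycle)
    syn_cycle = np.where(jitter == 2, np.char.add(syn_cycle.astype(str), "  "), syn_cycle)
    ps_name = np.where(
        drug_idx == TARGET_DRUG, syn_cycle,
        np.array(drug_names, dtype=object)[drug_idx],
    )
    conc_idx = (drug_idx + rng.integers(1, config.n_drugs, size=n)) % config.n_drugs
    conc_name = np.array(drug_names, dtype=object)[conc_idx]

    drug = pd.concat([
        pd.DataFrame({
            "primaryid": pids, "caseid": case_ids[src], "drug_seq": 1,
            "role_cod": "PS", "drugname": ps_name[src],
        }),
        pd.DataFrame({
            "primaryid": pids, "caseid": case_ids[src], "drug_seq": 2,
            "role_cod": "C", "drugname": conc_name[src],
        }),
    ], ignore_index=True)

    ev_report, ev_event = np.nonzero(occur)
    reac_base = pd.DataFrame({
        "report": ev_report,
        "pt": np.array(event_names, dtype=object)[ev_event],
    })
    reac = reac_base.merge(
        pd.DataFrame({"report": src, "primaryid": pids, "caseid": case_ids[src]}),
        on="report",
    )[["primaryid", "caseid", "pt"]]

    outc = pd.DataFrame({
        "primaryid": pids, "caseid": case_ids[src], "outc_cod": outcome[src],
    })
    ther = pd.DataFrame({
        "primaryid": pids, "caseid": case_ids[src], "dsg_drug_seq": 1,
        "start_dt": _date_to_int(start_dt[src].astype("datetime64[D]")),
    })

    # Split into quarters by the version's FDA date quarter membership: a
    # version belongs to the quarter of its own FDA date, clipped to range.
    q_bounds = [quarter_bounds(q) for q in config.quarters]
    q_of_version = np.zeros(len(pids), dtype=int)
    fda_days = fda_all.astype("datetime64[D]")
    for qi, (lo, hi) in enumerate(q_bounds):
        mask = fda_days >= np.datetime64(lo)
        q_of_version[mask] = qi
    version_quarter = {int(p): config.quarters[q] for p, q in zip(pids, q_of_version)}

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    frames = {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc, "THER": ther}
    for name, frame in frames.items():
        qcol = frame["primaryid"].map(version_quarter)
        for q in config.quarters:
            sub = frame[qcol == q].reset_index(drop=True)
            tables[(name, q)] = sub[FAERS_SCHEMAS[name]].copy()

    truth = GroundTruth(
        true_rr={k: float(v) for k, v in config.planted_rr.items()},
        true_onset_shape=float(config.onset_shape),
        true_onset_scale_days=float(config.onset_scale_days),
        duplicate_map=duplicate_map,
        canonical_version=canonical,
        drug_names=drug_names,
        event_names=event_names,
        pt_soc_map=pt_soc_map,
        report_drug={int(c): int(d) for c, d in zip(case_ids, drug_idx)},
        report_events={
            int(case_ids[i]): sorted(int(e) for e in np.nonzero(occur[i])[0])
            for i in range(n)
        },
        onset_lag_days={int(c): int(l) for c, l in zip(case_ids, lag_days)},
        target_case_ids=[int(c) for c in case_ids[drug_idx == TARGET_DRUG]],
    )
    return tables, truth


def write_faers_ascii(
    tables: dict[tuple[str, str], pd.DataFrame], directory: str | Path
) -> list[Path]:
    """Write one dollar-delimited text file per (table, quarter).

    The dialect has no quoting, so any field containing the delimiter is
    rejected rather than silently corrupted.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for (name, q), frame in sorted(tables.items()):
        if name not in FAERS_SCHEMAS:
            raise ValidationError(f"unknown FAERS table {name!r}")
        str_frame = frame.astype(str).replace("nan", "")
        for col in str_frame.columns:
            if str_frame[col].str.contains(re.escape(FAERS_DELIMITER)).any():
                raise ValidationError(
                    f"table {name} {q}: field in column {col!r} contains the "
                    f"delimiter {FAERS_DELIMITER!r}; the dialect has no quoting"
                )
        path = directory / f"{name}{file_suffix(q)}.txt"
        str_frame.to_csv(path, sep=FAERS_DELIMITER, index=False, lineterminator="\n")
        paths.append(path)
    return paths


def write_support_files(
    truth: GroundTruth, directory: str | Path
) -> dict[str, Path]:
    """PT->SOC map (TSV), synonym list, suicide-PT list, ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    pt_soc = directory / "pt_soc_map.tsv"
    pt_soc.write_text(
        "".join(f"{pt}\t{soc}\n" for pt, soc in sorted(truth.pt_soc_map.items()))
    )
    paths["pt_soc_map"] = pt_soc
    syn = directory / "synonyms.txt"
    syn.write_text("".join(f"{s}\n" for s in VORTIOXETINE_SYNONYMS))
    paths["synonyms"] = syn
    spt = directory / "suicide_pts.txt"
    spt.write_text("".join(f"{s}\n" for s in SUICIDE_PTS))
    paths["suicide_pts"] = spt
    gt = directory / "ground_truth.json"
    truth.to_json(gt)
    paths["ground_truth"] = gt
    return paths


def simulate_to_directory(
    config: SimulationConfig, directory: str | Path
) -> tuple[list[Path], GroundTruth]:
    """Simulate and write a complete analysis-ready bundle."""
    tables, truth = simulate_reports(config)
    paths = write_faers_ascii(tables, directory)
    write_support_files(truth, directory)
    return paths, truth
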