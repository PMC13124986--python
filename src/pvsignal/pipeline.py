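"""End-to-end run: ingest -> dedup -> select -> signals -> TTO -> subgroups.

All outputs are plain TSV/JSON with fixed column order, sorted rows and
fixed float formatting, so a re-run with the same inputs and configuration
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, ValidationError
from .constants import SUICIDE_PTS
from .ingest import (
    IngestReport,
    assemble_records,
    load_pt_soc_map,
    map_pt_to_soc,
    normalize_name,
    read_faers_ascii,
)
from .signals import build_cells, rank_signals, signal_table
from .subgroups import characterize, label_suicide_reports, suicide_subgroup_tables
from .temporal import cumulative_incidence, extract_onsets, fit_weibull

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = [
    "event", "n", "ror", "ror_lo95", "ror_hi95", "prr", "prr_chisq",
    "ebgm", "ebgm05", "ic", "ic025",
    "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps", "flag_positive",
]


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f",
                 lineterminator="\n")


def _load_lines(path: Path) -> tuple[str, ...]:
    return tuple(
        line.strip() for line in path.read_text().splitlines() if line.strip()
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle.

    Returns the manifest (stage counts, config echo, output paths).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = IngestReport()

    try:
        tables = read_faers_ascii(config.input_dir, list(config.quarters), report)
    except (OSError, ValidationError) as exc:
        raise RuntimeError(
            f"stage 'ingest' failed: {exc} — check input_dir and quarters "
            "in the configuration"
        ) from exc

    cohort = assemble_records(tables, config.synonyms, report)
    n_raw = report.rows_read.get("DEMO", 0)

    if config.pt_soc_map_path is None:
        raise ValidationError(
            "pipeline config key 'pt_soc_map_path' is required for SOC-level "
            "signal detection (MedDRA-style PT->SOC table, 2-column TSV)"
        )
    pt_soc_map = load_pt_soc_map(config.pt_soc_map_path)
    unmapped = sorted({
        pt for pt in cohort.reactions["pt"].unique()
        if map_pt_to_soc(pt, pt_soc_map) == "UNMAPPED"
    })
    if unmapped:
        logger.warning("%d PT(s) missing from the PT->SOC map", len(unmapped))
        report.unmapped_pts.extend(unmapped)

    suicide_pts = (
        _load_lines(Path(config.suicide_pt_path))
        if config.suicide_pt_path is not None else SUICIDE_PTS
    )

    # --- signal detection ---------------------------------------------------
    results = {}
    for level in ("PT", "SOC"):
        cells = build_cells(
            cohort.reactions, cohort.target_ids,
            n_target=cohort.n_target, n_total=cohort.n_reports,
            level=level, pt_soc_map=pt_soc_map,
        )
        frame = signal_table(
            cells, thresholds=config.thresholds,
            zero_policy=config.zero_cell_policy, yates=config.yates_correction,
        )
        results[level] = rank_signals(frame, by="n")

    wanted = {normalize_name(p) for p in suicide_pts}
    suicide_signals = results["PT"][
        results["PT"]["event"].map(normalize_name).isin(wanted)
    ].reset_index(drop=True)

    # --- time to onset ------------------------------------------------------
    onsets = extract_onsets(cohort, event_filter=config.tto_event_filter)
    tto_frame = pd.DataFrame()
    ci_frame = pd.DataFrame()
    if len(onsets) >= 10 and np.unique(onsets.onset_days).size >= 2:
        fit = fit_weibull(onsets, seed=config.seed)
        tto_frame = pd.DataFrame([{
            "n": len(onsets), "n_excluded": onsets.n_excluded,
            "median_days": fit.median_days,
            "q25_days": fit.q25_days, "q75_days": fit.q75_days,
            "weibull_shape": fit.shape, "weibull_scale_days": fit.scale,
            "shape_lo95": fit.beta_lo95, "shape_hi95": fit.beta_hi95,
            "classification": fit.classification,
        }])
        ci_frame = cumulative_incidence(onsets)
    else:
        logger.warning("too few onset values (%d) for a Weibull fit", len(onsets))

    # --- subgroups ----------------------------------------------------------
    suicide_ids = label_suicide_reports(cohort.reactions, list(suicide_pts))
    suicide_ids &= cohort.target_ids
    char_all = characterize(cohort, ids=cohort.target_ids)
    char_suicide = characterize(cohort, ids=suicide_ids)
    tests = suicide_subgroup_tables(cohort, suicide_ids, seed=config.seed)
    tests_frame = pd.DataFrame([{
        "factor": t.factor, "categories": "|".join(t.categories),
        "chi2": t.chi2, "df": t.df, "p_value": t.p_value,
        "test_used": t.test_used,
    } for t in tests])

    # --- write bundle -------------------------------------------------------
    outputs = {
        "cohort.tsv": cohort.records.assign(
            is_target=cohort.records["primaryid"].isin(cohort.target_ids),
            is_suicide=cohort.records["primaryid"].isin(suicide_ids),
        ),
        "signals_pt.tsv": results["PT"][SIGNAL_COLUMNS],
        "signals_soc.tsv": results["SOC"][SIGNAL_COLUMNS],
        "signals_suicide_pt.tsv": suicide_signals[SIGNAL_COLUMNS],
        "tto_weibull.tsv": tto_frame,
        "cumulative_incidence.tsv": ci_frame,
        "characteristics_all.tsv": char_all,
        "characteristics_suicide.tsv": char_suicide,
        "subgroup_tests.tsv": tests_frame,
    }
    paths = {}
    for name, frame in outputs.items():
        path = out_dir / name
        _write_tsv(frame, path)
        paths[name] = str(path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stage_counts": {
            "demo_rows_read": n_raw,
            "reports_after_dedup": cohort.n_reports,
            "duplicates_removed": report.duplicates_removed,
            "target_reports": cohort.n_target,
            "suicide_reports": len(suicide_ids),
            "onsets_retained": len(onsets),
            "onsets_excluded": onsets.n_excluded,
            "pt_events": int(len(results["PT"])),
            "soc_events": int(len(results["SOC"])),
            "positive_pt_signals": int(results["PT"]["flag_positive"].sum()),
        },
        "ingest_report": report.to_dict(),
        "outputs": paths,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    (out_dir / "subgroup_tests.json").write_text(
        json.dumps([
            {
                "factor": t.factor, "categories": list(t.categories),
                "counts": t.counts.tolist(), "chi2": t.chi2, "df": t.df,
                "p_value": t.p_value, "test_used": t.test_used,
            } for t in tests
        ], indent=1) + "\n"
    )
    return manifest
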