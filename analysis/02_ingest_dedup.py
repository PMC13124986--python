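"""Ingest the bundle, apply the FDA deduplication rule, select the cohort.

Checks the surviving versions against the generator's canonical
bookkeeping and writes the ingest counters to results/.
"""

import json

from _common import BUNDLE_DIR, QUARTERS, RESULTS_DIR, ensure_bundle

from pvsignal.constants import VORTIOXETINE_SYNONYMS
from pvsignal.ingest import IngestReport, assemble_records, read_faers_ascii
from pvsignal.synthetic import GroundTruth


def main() -> None:
    ensure_bundle()
    truth = GroundTruth.from_json(BUNDLE_DIR / "ground_truth.json")
    report = IngestReport()
    tables = read_faers_ascii(BUNDLE_DIR, list(QUARTERS), report)
    cohort = assemble_records(tables, VORTIOXETINE_SYNONYMS, report)

    kept = dict(zip(cohort.records["caseid"].astype(int),
                    cohort.records["primaryid"].astype(int)))
    mismatches = sum(
        1 for cid, pid in truth.canonical_version.items() if kept.get(cid) != pid
    )
    summary = {
        "demo_versions_read": report.rows_read.get("DEMO", 0),
        "reports_after_dedup": cohort.n_reports,
        "duplicates_removed": report.duplicates_removed,
        "dedup_mismatches_vs_truth": mismatches,
        "target_reports": cohort.n_target,
        "target_truth": len(truth.target_case_ids),
        "ingest": report.to_dict(),
    }
    (RESULTS_DIR / "ingest_summary.json").write_text(
        json.dumps(summary, indent=1) + "\n"
    )
    print(f"read {summary['demo_versions_read']:,} DEMO versions -> "
          f"{summary['reports_after_dedup']:,} deduplicated reports "
          f"({summary['duplicates_removed']:,} removed, "
          f"{mismatches} mismatches vs ground truth)")
    print(f"target-drug primary-suspect cohort: {cohort.n_target:,} reports "
          f"(ground truth {len(truth.target_case_ids):,})")


if __name__ == "__main__":
    main()
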