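"""Disproportionality analysis of the study bundle at PT and SOC level.

Computes all four algorithms per event, applies the combined
positive-signal rule, and compares flagged events with the planted pairs.
"""

from _common import BUNDLE_DIR, QUARTERS, RESULTS_DIR, ensure_bundle

from pvsignal.constants import SUICIDE_PTS, VORTIOXETINE_SYNONYMS
from pvsignal.ingest import assemble_records, load_pt_soc_map, normalize_name, read_faers_ascii
from pvsignal.pipeline import SIGNAL_COLUMNS
from pvsignal.signals import build_cells, rank_signals, signal_table
from pvsignal.synthetic import GroundTruth


def main() -> None:
    ensure_bundle()
    truth = GroundTruth.from_json(BUNDLE_DIR / "ground_truth.json")
    tables = read_faers_ascii(BUNDLE_DIR, list(QUARTERS))
    cohort = assemble_records(tables, VORTIOXETINE_SYNONYMS)
    pt_soc = load_pt_soc_map(BUNDLE_DIR / "pt_soc_map.tsv")

    for level, name in (("PT", "signals_pt.tsv"), ("SOC", "signals_soc.tsv")):
        cells = build_cells(
            cohort.reactions, cohort.target_ids, cohort.n_target,
            cohort.n_reports, level=level, pt_soc_map=pt_soc,
        )
        frame = rank_signals(signal_table(cells), by="n")
        frame[SIGNAL_COLUMNS].to_csv(
            RESULTS_DIR / name, sep="\t", index=False, float_format="%.4f",
        )
        pos = frame[frame["flag_positive"]]
        print(f"{level}: {len(frame)} events, {len(pos)} positive "
              f"by the all-four rule -> results/{name}")
        if level == "PT":
            planted_events = {truth.event_names[e] for (_, e) in truth.true_rr}
            flagged = set(pos["event"])
            print(f"  planted events recovered: "
                  f"{len(planted_events & flagged)}/{len(planted_events)}")
            suicide = frame[
                frame["event"].map(normalize_name).isin(
                    {normalize_name(p) for p in SUICIDE_PTS}
                )
            ]
            print("  suicide-related PTs (n, ROR, EBGM, positive):")
            for _, r in suicide.iterrows():
                print(f"    {r['event']:<28} {r['n']:>4} "
                      f"{r['ror']:>7.2f} {r['ebgm']:>7.2f} "
                      f"{'+' if r['flag_positive'] else '-'}")


if __name__ == "__main__":
    main()
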