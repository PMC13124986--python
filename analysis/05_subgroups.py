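"""Descriptive characterisation and suicide-vs-other subgroup tests on the
synthetic cohort.

The generator draws suicide PTs independently of demographics, so the
expected finding here is *no* association — a calibration check on the
testing machinery rather than a planted effect.
"""

import pandas as pd

from _common import BUNDLE_DIR, QUARTERS, RESULTS_DIR, ensure_bundle

from pvsignal.constants import SUICIDE_PTS, VORTIOXETINE_SYNONYMS
from pvsignal.ingest import assemble_records, read_faers_ascii
from pvsignal.subgroups import characterize, label_suicide_reports, suicide_subgroup_tables


def main() -> None:
    ensure_bundle()
    tables = read_faers_ascii(BUNDLE_DIR, list(QUARTERS))
    cohort = assemble_records(tables, VORTIOXETINE_SYNONYMS)
    suicide_ids = label_suicide_reports(cohort.reactions, SUICIDE_PTS)
    suicide_ids &= cohort.target_ids

    characterize(cohort, ids=cohort.target_ids).to_csv(
        RESULTS_DIR / "characteristics_all.tsv", sep="\t", index=False,
    )
    characterize(cohort, ids=suicide_ids).to_csv(
        RESULTS_DIR / "characteristics_suicide.tsv", sep="\t", index=False,
    )
    tests = suicide_subgroup_tables(cohort, suicide_ids, seed=0)
    pd.DataFrame([{
        "factor": t.factor, "categories": "|".join(t.categories),
        "chi2": t.chi2, "df": t.df, "p_value": t.p_value,
        "test_used": t.test_used,
    } for t in tests]).to_csv(
        RESULTS_DIR / "subgroup_tests.tsv", sep="\t", index=False,
        float_format="%.4f",
    )
    print(f"target cohort {cohort.n_target:,}; "
          f"suicide-related {len(suicide_ids):,} "
          f"({100 * len(suicide_ids) / cohort.n_target:.1f}%)")
    for t in tests:
        verdict = "associated" if t.p_value < 0.05 else "no association"
        print(f"  {t.factor:<7} chi2={t.chi2:6.2f} df={t.df} "
              f"p={t.p_value:.3f} ({t.test_used}) -> {verdict}")


if __name__ == "__main__":
    main()
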