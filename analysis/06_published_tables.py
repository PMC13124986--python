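"""Reanalysis of the published vortioxetine suicide-cohort tables.

The printed demographic contingency tables and cohort counts are fixed
inputs; feeding them through the package's own test and characterisation
routines reproduces the published chi-square statistics (48.77 for sex,
30.17 for age, 0.88 with p = 0.64 for weight) and proportions (60.83%
female overall, 55.62% female among suicide-related reports).
"""

import json

from _common import RESULTS_DIR, ensure_bundle

from pvsignal.subgroups import proportion_pct, subgroup_test

SEX_TABLE = [[7624, 708], [3180, 459]]
AGE_TABLE = [[982, 109], [4102, 570], [965, 75], [86, 2]]
WEIGHT_TABLE = [[157, 14], [1967, 202], [340, 40]]


def main() -> None:
    ensure_bundle()
    out = {}
    for factor, table, cats in (
        ("sex", SEX_TABLE, ("Female", "Male")),
        ("age", AGE_TABLE, ("<18", "18-64", "65-85", ">85")),
        ("weight", WEIGHT_TABLE, ("<50", "50-100", ">100")),
    ):
        res = subgroup_test(table, factor=factor, categories=cats,
                            policy="pearson")
        out[factor] = {"chi2": round(res.chi2, 2), "df": res.df,
                       "p_value": round(res.p_value, 4)}
        print(f"{factor:<7} chi2={res.chi2:6.2f} df={res.df} "
              f"p={res.p_value:.4f}")
    out["female_pct_all"] = proportion_pct(8332, 13698)
    out["female_pct_suicide"] = proportion_pct(708, 1273)
    print(f"female share: {out['female_pct_all']}% of 13,698 reports; "
          f"{out['female_pct_suicide']}% of 1,273 suicide-related reports")
    (RESULTS_DIR / "published_reanalysis.json").write_text(
        json.dumps(out, indent=1) + "\n"
    )


if __name__ == "__main__":
    main()
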