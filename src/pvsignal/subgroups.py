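"""Descriptive characterisation and subgroup contingency testing.

Cohorts are summarised per category (sex, binned age and weight, country,
reporter, outcome, reporting year) with missingness shown as its own row.
Association between suicide-related reporting and a demographic factor is
tested on the r x 2 table of (non-suicide, suicide) counts per category —
Pearson chi-square without continuity correction, switching to Fisher's
exact test when any expected count falls below a configurable threshold.
Missing-category rows are excluded from the tests but kept in descriptive
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ValidationError
from .ingest import Cohort, normalize_name

#: Age bin edges by scheme; labels are half-open except noted boundaries.
AGE_SCHEMES = {
    # bins of the demographic tables: <18, 18-64, 65-85, >85
    "table": (("<18", 0.0, 18.0), ("18-64", 18.0, 65.0),
              ("65-85", 65.0, 85.0 + 1e-9), (">85", 85.0 + 1e-9, np.inf)),
    # FDA antidepressant warning bins: <=24 (includes exactly 24.0), 25-64, >=65
    "fda_warning": (("<=24", 0.0, 24.0 + 1e-9), ("25-64", 24.0 + 1e-9, 65.0),
                    (">=65", 65.0, np.inf)),
}

WEIGHT_BINS = (("<50", 0.0, 50.0), ("50-100", 50.0, 100.0 + 1e-9),
               (">100", 100.0 + 1e-9, np.inf))

MISSING = "Missing"


@dataclass(frozen=True)
class SubgroupTable:
    """r x 2 contingency test result for one factor."""

    factor: str
    categories: tuple[str, ...]
    counts: np.ndarray          # shape (r, 2): (non-suicide, suicide)
    chi2: float
    df: int
    p_value: float
    test_used: str              # "pearson" or "fisher"


def label_suicide_reports(
    reactions: pd.DataFrame, suicide_pts: list[str] | tuple[str, ...]
) -> set[str]:
    """Primary IDs of reports carrying at least one suicide-related PT."""
    if not suicide_pts:
        raise ValidationError("suicide PT list must be non-empty")
    wanted = {normalize_name(p) for p in suicide_pts}
    if "pt_norm" in reactions.columns:
        norm = reactions["pt_norm"]
    else:
        norm = reactions["pt"].map(normalize_name)
    return set(reactions.loc[norm.isin(wanted), "primaryid"].astype(str))


def age_rebin(ages_years: pd.Series, scheme: str = "table") -> pd.Series:
    """Deterministic age binning; NaN -> 'Missing'.

    Boundary ages land in the lower-bounded bin that contains them: with
    the FDA-warning scheme, exactly 24.0 belongs to "<=24".
    """
    if scheme not in AGE_SCHEMES:
        raise ValidationError(
            f"unknown age scheme {scheme!r}; choose one of {sorted(AGE_SCHEMES)}"
        )
    bins = AGE_SCHEMES[scheme]
    out = pd.Series(MISSING, index=ages_years.index, dtype=object)
    for label, lo, hi in bins:
        mask = ages_years.notna() & (ages_years >= lo) & (ages_years < hi)
        out[mask] = label
    return out


def weight_rebin(weights_kg: pd.Series) -> pd.Series:
    out = pd.Series(MISSING, index=weights_kg.index, dtype=object)
    for label, lo, hi in WEIGHT_BINS:
        mask = weights_kg.notna() & (weights_kg >= lo) & (weights_kg < hi)
        out[mask] = label
    return out


def proportion_pct(count: int, total: int) -> float:
    """Percentage to two decimals, as printed in descriptive tables."""
    return round(100.0 * count / total, 2)


def characterize(
    cohort: Cohort,
    ids: set[str] | None = None,
    top_k_countries: int = 5,
) -> pd.DataFrame:
    """Per-category counts and percentages for the standard factors.

    Returns a tidy frame (factor, category, count, proportion_pct) whose
    counts per factor sum to the cohort total (missing included).
    """
    rec = cohort.records
    if ids is not None:
        rec = rec[rec["primaryid"].isin(ids)]
    total = len(rec)
    rows: list[dict] = []

    def add(factor: str, series: pd.Series, order: list[str] | None = None) -> None:
        counts = series.value_counts()
        cats = order if order is not None else sorted(counts.index)
        for cat in cats:
            c = int(counts.get(cat, 0))
            rows.append({
                "factor": factor, "category": cat, "count": c,
                "proportion_pct": proportion_pct(c, total) if total else np.nan,
            })

    add("sex", rec["sex"].fillna(MISSING), ["Female", "Male", MISSING])
    add("age", age_rebin(rec["age_years"]),
        [b[0] for b in AGE_SCHEMES["table"]] + [MISSING])
    add("weight", weight_rebin(rec["weight_kg"]),
        [b[0] for b in WEIGHT_BINS] + [MISSING])
    country = rec["country"].replace("", MISSING)
    top = country.value_counts().head(top_k_countries).index.tolist()
    add("country", country.where(country.isin(top), other="Other"),
        top + ["Other"])
    reporter = rec["reporter"].replace(
        {"CN": "Consumer", "MD": "Physician", "OT": "Healthcare professional",
         "PH": "Pharmacist", "": MISSING}
    )
    add("reporter", reporter)
    if total:
        add("reporting_year", rec["fda_date"].dt.year.astype("Int64").astype(str))
    # outcomes: one report may carry several outcome codes; count per report
    outc = cohort.outcomes
    outc = outc[outc["primaryid"].astype(str).isin(set(rec["primaryid"]))]
    outcome_counts = outc.groupby("outc_cod")["primaryid"].nunique()
    for code in sorted(outcome_counts.index):
        c = int(outcome_counts[code])
        rows.append({
            "factor": "outcome", "category": code, "count": c,
            "proportion_pct": proportion_pct(c, total) if total else np.nan,
        })
    return pd.DataFrame(rows, columns=["factor", "category", "count", "proportion_pct"])


def subgroup_test(
    counts: np.ndarray | list[list[int]],
    factor: str = "",
    categories: tuple[str, ...] | None = None,
    policy: str = "auto",
    expected_min: float = 5.0,
    seed: int = 0,
) -> SubgroupTable:
    """Test an r x 2 (non-suicide, suicide) table.

    ``policy``: "pearson" forces the uncorrected chi-square, "fisher"
    forces the exact test, "auto" uses Fisher when any expected count is
    below ``expected_min``. All-zero category rows are dropped (with the
    degrees of freedom adjusted accordingly). ``seed`` fixes the
    resampling RNG of the r x 2 (r > 2) exact test.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValidationError("counts must be an r x 2 matrix")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    nonzero = counts.sum(axis=1) > 0
    if categories is not None:
        categories = tuple(c for c, keep in zip(categories, nonzero) if keep)
    counts = counts[nonzero]
    r = counts.shape[0]
    if r < 2:
        raise ValidationError("need at least 2 non-empty categories")
    if np.any(counts.sum(axis=0) == 0):
        raise ValidationError("a column of the contingency table is all zero")

    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    use_fisher = policy == "fisher" or (
        policy == "auto" and np.any(expected < expected_min)
    )
    if policy not in {"auto", "pearson", "fisher"}:
        raise ValidationError(f"unknown test policy {policy!r}")

    chi2, p_pearson, df, _ = stats.chi2_contingency(counts, correction=False)
    if use_fisher:
        # 2x2: exact hypergeometric; r x 2: seeded Monte-Carlo resampling
        if counts.shape == (2, 2):
            p = float(stats.fisher_exact(counts.astype(int)).pvalue)
        else:
            method = stats.MonteCarloMethod(
                rng=np.random.default_rng(seed), n_resamples=20_000
            )
            p = float(stats.fisher_exact(counts.astype(int), method=method).pvalue)
        test_used = "fisher"
    else:
        p = float(p_pearson)
        test_used = "pearson"
    return SubgroupTable(
        factor=factor,
        categories=categories if categories is not None else tuple(
            str(i) for i in range(r)
        ),
        counts=counts.astype(int),
        chi2=float(chi2),
        df=int(df),
        p_value=float(p),
        test_used=test_used,
    )


def suicide_subgroup_tables(
    cohort: Cohort,
    suicide_ids: set[str],
    policy: str = "auto",
    age_scheme: str = "table",
    seed: int = 0,
) -> list[SubgroupTable]:
    """Sex, age and weight tests for suicide-related vs other target reports."""
    rec = cohort.records
    rec = rec[rec["primaryid"].isin(cohort.target_ids)].copy()
    is_suicide = rec["primaryid"].isin(suicide_ids)

    out: list[SubgroupTable] = []
    factors = {
        "sex": rec["sex"].fillna(MISSING),
        "age": age_rebin(rec["age_years"], scheme=age_scheme),
        "weight": weight_rebin(rec["weight_kg"]),
    }
    for factor, series in factors.items():
        tab = pd.crosstab(series, is_suicide)
        tab = tab.reindex(columns=[False, True], fill_value=0)
        tab = tab[tab.index != MISSING]          # tests exclude missing
        cats = tuple(str(c) for c in tab.index)
        out.append(
            subgroup_test(tab.to_numpy(), factor=factor, categories=cats,
                          policy=policy, seed=seed)
        )
    return out
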