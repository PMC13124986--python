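"""Disproportionality statistics against arithmetic, sampling and
numerical-integration oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from pvsignal import SignalThresholds, ValidationError
from pvsignal.signals import (
    ContingencyCell,
    MgpsPrior,
    SignalResult,
    bcpnn_stats,
    build_cells,
    compute_signal,
    fit_mgps_prior,
    flag_signals,
    mgps_stats,
    pearson_chisq,
    prr_stats,
    rank_signals,
    ror_stats,
    signal_table,
)

REF_CELL = ContingencyCell("ref", a=20, b=80, c=100, d=9800)
FLAT_PRIOR = MgpsPrior(alpha1=1.0, beta1=1.0, alpha2=1.0, beta2=1.0, weight=0.5)


def reactions_frame(pairs):
    """pairs: (primaryid, pt) tuples."""
    frame = pd.DataFrame(pairs, columns=["primaryid", "pt"])
    frame["pt_norm"] = frame["pt"].str.casefold()
    frame["caseid"] = frame["primaryid"]
    return frame


class TestBuildCells:
    def test_simple_counts(self):
        reac = reactions_frame(
            [(str(i), "Nausea") for i in range(4)]
            + [(str(i), "Headache") for i in range(4, 30)]
        )
        target = {str(i) for i in range(10)}
        cells = {c.event: c for c in build_cells(reac, target, 10, 50)}
        nausea = cells["Nausea"]
        assert (nausea.a, nausea.b, nausea.c, nausea.d) == (4, 6, 0, 40)

    def test_margin_conservation_on_synthetic(self, cohort):
        cells = build_cells(
            cohort.reactions, cohort.target_ids, cohort.n_target, cohort.n_reports
        )
        event_totals = cohort.reactions.groupby(
            cohort.reactions["pt"].str.casefold()
        )["primaryid"].nunique()
        for cell in cells:
            assert cell.a + cell.b == cohort.n_target
            assert cell.a + cell.c == event_totals[cell.event.casefold()]
            assert cell.n == cohort.n_reports

    def test_soc_level_counts_once_per_report(self):
        # one report with two PTs in the same SOC contributes a single count
        reac = reactions_frame([("1", "Nausea"), ("1", "Vomiting"), ("2", "Nausea")])
        soc_map = {"nausea": "GI", "vomiting": "GI"}
        cells = build_cells(reac, {"1"}, 1, 10, level="SOC", pt_soc_map=soc_map)
        (cell,) = cells
        assert cell.event == "GI" and cell.a == 1 and cell.c == 1

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            build_cells(reactions_frame([]), set(), 0, 0)

    def test_planted_pair_rr_within_20pct(self, cohort, truth):
        cells = build_cells(
            cohort.reactions, cohort.target_ids, cohort.n_target, cohort.n_reports
        )
        cell = next(c for c in cells if c.event == truth.event_names[12])
        rr = (cell.a / (cell.a + cell.b)) / (cell.c / (cell.c + cell.d))
        assert rr == pytest.approx(truth.true_rr[(0, 12)], rel=0.25)


class TestRor:
    def test_symmetric_cell_is_unity(self):
        ror, lo, hi = ror_stats(ContingencyCell("x", 10, 10, 10, 10))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_cross_ratio_arithmetic(self):
        ror, lo, hi = ror_stats(REF_CELL)
        assert ror == pytest.approx(24.5)
        assert lo < ror < hi

    def test_zero_cell_undefined_by_default(self):
        ror, lo, hi = ror_stats(ContingencyCell("x", 0, 10, 10, 100))
        assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)

    def test_haldane_policy_defines_zero_cells(self):
        ror, lo, hi = ror_stats(
            ContingencyCell("x", 0, 10, 10, 100), zero_policy="haldane"
        )
        assert ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))


class TestPrr:
    def test_equal_proportions(self):
        prr, chisq = prr_stats(ContingencyCell("x", 10, 90, 100, 900))
        assert prr == pytest.approx(1.0)
        assert chisq == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        prr, chisq = prr_stats(REF_CELL)
        assert prr == pytest.approx(19.8)
        assert chisq > 0

    def test_no_event_in_background_undefined(self):
        prr, _ = prr_stats(ContingencyCell("x", 5, 5, 0, 100))
        assert math.isnan(prr)

    def test_chisq_matches_scipy(self):
        table = np.array([[20, 80], [100, 9800]])
        expect = stats.chi2_contingency(table, correction=False)[0]
        assert pearson_chisq(REF_CELL) == pytest.approx(expect, rel=1e-12)
        expect_yates = stats.chi2_contingency(table, correction=True)[0]
        assert pearson_chisq(REF_CELL, yates=True) == pytest.approx(
            expect_yates, rel=1e-12
        )

    def test_null_chisq_calibration(self):
        """Under independence ~5% of cells exceed the 3.84 critical value."""
        rng = np.random.default_rng(42)
        n_target, n_other, p = 2000, 18000, 0.01
        hits = 0
        n_cells = 1000
        for _ in range(n_cells):
            a = rng.binomial(n_target, p)
            c = rng.binomial(n_other, p)
            cell = ContingencyCell("x", a, n_target - a, c, n_other - c)
            if pearson_chisq(cell) > 3.84:
                hits += 1
        assert 0.02 < hits / n_cells < 0.08

    def test_ror_prr_agree_for_rare_events(self):
        """Rare-event approximation: ROR ~ PRR when a << a+b and c << c+d."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            ab, cd = 10_000, 1_000_000
            a = int(rng.integers(1, 80))           # a/(a+b) < 0.01
            c = int(rng.integers(1, 8000))
            cell = ContingencyCell("x", a, ab - a, c, cd - c)
            ror, _, _ = ror_stats(cell)
            prr, _ = prr_stats(cell)
            assert ror == pytest.approx(prr, rel=0.05)


class TestBcpnn:
    def test_independence_point_near_zero(self):
        # a*N == (a+b)(a+c): 100*10000 == 1000*1000
        cell = ContingencyCell("x", 100, 900, 900, 8100)
        ic, ic025 = bcpnn_stats(cell)
        assert abs(ic) < 0.05
        assert ic025 < ic

    def test_deficit_direction(self):
        ic, _ = bcpnn_stats(ContingencyCell("x", 0, 500, 500, 9000))
        assert ic < 0

    def test_ic025_matches_monte_carlo_posterior(self):
        """Closed form vs 1e5 posterior draws of the rate-ratio gamma."""
        a, e = REF_CELL.a, REF_CELL.expected
        rng = np.random.default_rng(123)
        draws = np.log2(rng.gamma(a + 0.5, 1.0, 100_000) / (e + 0.5))
        _, ic025 = bcpnn_stats(REF_CELL)
        assert ic025 == pytest.approx(float(np.quantile(draws, 0.025)), abs=0.05)


def cell_with_expected(name: str, a: int, e: float, m: int = 5000,
                       n: int = 10_000_000) -> ContingencyCell:
    """Consistent 2x2 whose independence expectation (a+b)(a+c)/N is ~e."""
    ac = int(round(e * n / m))
    c = max(ac - a, 0)
    return ContingencyCell(name, a, m - a, c, n - m - c)


class TestMgps:
    def make_null_cells(self, n_cells=400, seed=5):
        rng = np.random.default_rng(seed)
        e = rng.uniform(0.5, 30.0, n_cells)
        a = rng.poisson(e)
        return [
            cell_with_expected(f"e{i}", int(ai), float(ei))
            for i, (ai, ei) in enumerate(zip(a, e))
        ]

    def test_prior_recovery_null(self):
        """All rate ratios 1 -> fitted prior mean near 1."""
        cells = self.make_null_cells()
        prior = fit_mgps_prior(cells)
        assert 0.8 <= prior.mean <= 1.25

    def test_prior_recovery_two_components(self):
        """90% null / 10% tenfold cells -> weight lands on the high component."""
        rng = np.random.default_rng(17)
        n_cells = 2000
        e = rng.uniform(1.0, 30.0, n_cells)
        lam = np.where(rng.random(n_cells) < 0.10, 10.0, 1.0)
        a = rng.poisson(lam * e)
        cells = [
            cell_with_expected(f"e{i}", int(ai), float(ei))
            for i, (ai, ei) in enumerate(zip(a, e))
        ]
        prior = fit_mgps_prior(cells)
        means = {prior.weight: prior.alpha1 / prior.beta1,
                 1 - prior.weight: prior.alpha2 / prior.beta2}
        w_high = min(
            (w for w, m in means.items() if m > 3), default=0.0
        )
        assert 0.03 <= w_high <= 0.25

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValidationError):
            fit_mgps_prior([REF_CELL])

    def test_ebgm_matches_numerical_integration(self):
        """EBGM vs quad integration of log2(lambda) over the posterior."""
        cells = self.make_null_cells(60, seed=9)
        prior = fit_mgps_prior(cells)
        for cell in cells[:10] + [REF_CELL]:
            ebgm, _ = mgps_stats(cell, prior)
            oracle = _ebgm_by_integration(cell, prior)
            assert ebgm == pytest.approx(oracle, rel=0.01)

    def test_no_signal_cell_under_unit_prior(self):
        # a equals its expectation; prior concentrated at 1 keeps EBGM at 1
        prior = MgpsPrior(alpha1=200.0, beta1=200.0, alpha2=200.0,
                          beta2=200.0, weight=0.5)
        cell = ContingencyCell("x", 50, 950, 4950, 94050)
        assert cell.expected == pytest.approx(50, rel=0.01)
        ebgm, _ = mgps_stats(cell, prior)
        assert ebgm == pytest.approx(1.0, abs=0.05)

    def test_shrinkage_toward_diffuse_prior(self):
        """A strong observed ratio is pulled toward, not past, the data."""
        cell = ContingencyCell("x", 200, 800, 2000, 97000)
        ratio = cell.a / cell.expected
        ebgm, ebgm05 = mgps_stats(cell, FLAT_PRIOR)
        assert 0.8 * ratio <= ebgm <= ratio * 1.02
        assert ebgm05 < ebgm

    def test_ebgm05_below_ebgm_and_shrinkage_property(self, cohort):
        """Under a unit-mean diffuse prior the posterior mean of the rate
        ratio lies between the observed ratio and 1 (shrinkage never
        overshoots); the geometric mean EBGM sits at or below that mean
        (Jensen) with its 5th percentile below it. With a fitted mixture a
        cell can legitimately be pulled toward the signal component, so the
        overshoot check pins the prior to the unit-mean one."""
        cells = build_cells(
            cohort.reactions, cohort.target_ids, cohort.n_target, cohort.n_reports
        )
        prior = fit_mgps_prior(cells)
        for cell in cells:
            if cell.a == 0:
                continue
            ebgm_fit, ebgm05_fit = mgps_stats(cell, prior)
            assert ebgm05_fit < ebgm_fit
            ebgm, _ = mgps_stats(cell, FLAT_PRIOR)
            # flat prior: posterior is Gamma(1 + a, 1 + E)
            post_mean = (1 + cell.a) / (1 + cell.expected)
            obs = cell.a / cell.expected
            assert abs(math.log(post_mean)) <= abs(math.log(obs)) + 1e-12
            assert ebgm <= post_mean * (1 + 1e-9)


def _ebgm_by_integration(cell: ContingencyCell, prior: MgpsPrior) -> float:
    a, e = cell.a, cell.expected
    comps = [
        (prior.weight, prior.alpha1, prior.beta1),
        (1 - prior.weight, prior.alpha2, prior.beta2),
    ]
    log_marg = [
        math.log(w + 1e-300) + stats.nbinom.logpmf(a, al, be / (be + e))
        for w, al, be in comps
    ]
    norm = np.logaddexp(*log_marg)
    q = [math.exp(l - norm) for l in log_marg]

    # integrate log(lambda) against each component posterior over its own
    # bulk (a single quad over the union can miss a narrow spike)
    val = 0.0
    for qi, (_, al, be) in zip(q, comps):
        shape, scale = al + a, 1 / (be + e)
        lo = stats.gamma.ppf(1e-13, shape, scale=scale)
        hi = stats.gamma.ppf(1 - 1e-13, shape, scale=scale)
        part, _ = integrate.quad(
            lambda lam: math.log(lam) * stats.gamma.pdf(lam, shape, scale=scale),
            lo, hi, limit=500,
        )
        val += qi * part
    return math.exp(val)


class TestFlagsAndRanking:
    def test_minimum_count_rule(self):
        draft = SignalResult(
            event="x", a=2, b=8, c=1, d=989, ror=100, ror_lo95=10, ror_hi95=1000,
            prr=90, prr_chisq=100, ic=3, ic025=2, ebgm=50, ebgm05=20,
        )
        flagged = flag_signals(draft)
        assert not flagged.flag_ror and not flagged.flag_prr
        assert flagged.flag_bcpnn and flagged.flag_mgps
        assert not flagged.flag_positive

    def test_reference_cell_all_four_positive(self):
        result = compute_signal(REF_CELL, FLAT_PRIOR)
        assert result.flag_ror and result.flag_prr
        assert result.flag_bcpnn and result.flag_mgps
        assert result.flag_positive

    def test_independence_cell_negative(self):
        cell = ContingencyCell("x", 100, 900, 900, 8100)
        assert not compute_signal(cell, FLAT_PRIOR).flag_positive

    def test_thresholds_configurable(self):
        strict = SignalThresholds(ebgm05_min=1e9)
        assert not compute_signal(REF_CELL, FLAT_PRIOR, strict).flag_mgps

    def test_rank_tie_break_lexicographic(self):
        frame = pd.DataFrame(
            {"event": ["zeta", "alpha", "mid"], "n": [9, 9, 5],
             "ror": [1.0, 2.0, 3.0], "ebgm": [1.0, 1.0, 1.0]}
        )
        out = rank_signals(frame, by="n")
        assert out["event"].tolist() == ["alpha", "zeta", "mid"]

    def test_rank_empty_and_unknown_key(self):
        empty = pd.DataFrame(columns=["event", "n", "ror", "ebgm"])
        assert rank_signals(empty).empty
        with pytest.raises(ValidationError):
            rank_signals(empty, by="banana")

    def test_planted_signal_ranks_first_by_ror(self, cohort, truth):
        cells = build_cells(
            cohort.reactions, cohort.target_ids, cohort.n_target, cohort.n_reports
        )
        frame = signal_table(cells)
        top = rank_signals(frame, by="ror").iloc[0]
        assert top["event"] in {truth.event_names[12], truth.event_names[0]}
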