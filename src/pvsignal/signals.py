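"""Disproportionality signal detection on (drug, event) contingency cells.

For each event the 2x2 cell counts reports with/without the target drug and
with/without the event:

    ======================  =========  ============
                            event      other events
    target drug             a          b
    all other drugs         c          d
    ======================  =========  ============

Four algorithms are computed per cell:

* **ROR** — reporting odds ratio ``ad/bc`` with a Woolf (log-normal) 95% CI.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Pearson chi-square of the 2x2 (no continuity correction by default).
* **BCPNN IC** — information component ``log2((a+0.5)/(E+0.5))`` with
  ``E = (a+b)(a+c)/N``, the gamma-Poisson shrinkage variant: the posterior
  of the observed/expected ratio is Gamma(a+0.5, rate E+0.5) and IC025 is
  its 2.5th percentile via a normal approximation on the log2 scale.
* **MGPS EBGM** — empirical-Bayes geometric mean of the Poisson rate ratio
  under a two-component gamma mixture prior fitted to all cells by marginal
  maximum likelihood; EBGM05 is the posterior 5th percentile.

An event is a *positive signal* only when all four *algorithm-specific
criteria hold simultaneously* (configurable thresholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .config import SignalThresholds, ValidationError
from .ingest import map_pt_to_soc

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyCell:
    """2x2 counts for one (target drug, event) pair."""

    event: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValidationError("contingency table is empty (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def build_cells(
    reactions: pd.DataFrame,
    target_ids: set[str],
    n_target: int,
    n_total: int,
    level: str = "PT",
    pt_soc_map: dict[str, str] | None = None,
) -> list[ContingencyCell]:
    """One cell per event at PT or SOC level.

    ``reactions`` is long-format with unique (primaryid, pt_norm) rows over
    the *whole* deduplicated background (target and non-target reports).
    At SOC level a report contributes at most once per SOC no matter how
    many of its PTs map there.
    """
    if n_total <= 0:
        raise ValidationError("background is empty")
    if level not in {"PT", "SOC"}:
        raise ValidationError(f"unknown level {level!r}")
    work = reactions[["primaryid", "pt", "pt_norm"]].copy()
    if level == "SOC":
        if pt_soc_map is None:
            raise ValidationError("SOC level requires a PT->SOC map")
        work["event"] = work["pt"].map(lambda p: map_pt_to_soc(p, pt_soc_map))
        work = work.drop_duplicates(["primaryid", "event"])
    else:
        # display the first spelling seen for each normalised PT
        display = work.drop_duplicates("pt_norm").set_index("pt_norm")["pt"]
        work["event"] = work["pt_norm"].map(display)
        work = work.drop_duplicates(["primaryid", "event"])
    is_target = work["primaryid"].isin(target_ids)
    totals = work.groupby("event", sort=True)["primaryid"].nunique()
    a_counts = (
        work[is_target].groupby("event", sort=True)["primaryid"].nunique()
    )
    cells = []
    for event, total in totals.items():
        a = int(a_counts.get(event, 0))
        c = int(total) - a
        cells.append(
            ContingencyCell(
                event=str(event), a=a, b=n_target - a,
                c=c, d=n_total - n_target - c,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# per-algorithm statistics


def _apply_zero_policy(cell: ContingencyCell, policy: str) -> tuple[float, float, float, float] | None:
    """Return (a, b, c, d) as floats, or None when undefined under policy."""
    counts = (cell.a, cell.b, cell.c, cell.d)
    if 0 not in counts:
        return tuple(float(x) for x in counts)
    if policy == "haldane":
        return tuple(x + 0.5 for x in counts)
    if policy == "undefined":
        return None
    raise ValidationError(f"unknown zero-cell policy {policy!r}")


def ror_stats(
    cell: ContingencyCell, zero_policy: str = "undefined"
) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% CI; NaNs when undefined."""
    counts = _apply_zero_policy(cell, zero_policy)
    if counts is None:
        return (math.nan, math.nan, math.nan)
    a, b, c, d = counts
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


def pearson_chisq(cell: ContingencyCell, yates: bool = False) -> float:
    """Chi-square of the 2x2; NaN when a margin is zero."""
    a, b, c, d = (float(x) for x in (cell.a, cell.b, cell.c, cell.d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff**2 / denom


def prr_stats(
    cell: ContingencyCell, yates: bool = False, zero_policy: str = "undefined"
) -> tuple[float, float]:
    """Proportional reporting ratio and its Pearson chi-square."""
    chisq = pearson_chisq(cell, yates=yates)
    a, b, c, d = (float(x) for x in (cell.a, cell.b, cell.c, cell.d))
    if zero_policy == "haldane" and 0 in (cell.a, cell.b, cell.c, cell.d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if a + b == 0 or c + d == 0 or c == 0:
        return (math.nan, chisq)
    return ((a / (a + b)) / (c / (c + d)), chisq)


def bcpnn_stats(cell: ContingencyCell) -> tuple[float, float]:
    """Shrinkage information component and its lower 95% credible bound.

    Posterior of the rate ratio: lambda | a ~ Gamma(a + 0.5, rate E + 0.5);
    IC = log2((a+0.5)/(E+0.5)) (posterior shape/rate ratio), IC025 from the
    normal approximation to log2(lambda): mean psi(a+0.5)/ln2 - log2(E+0.5),
    sd sqrt(psi'(a+0.5))/ln2.
    """
    a = cell.a
    e = cell.expected
    shape = a + 0.5
    rate = e + 0.5
    ic = math.log2(shape / rate)
    mu = special.digamma(shape) / math.log(2) - math.log2(rate)
    sd = math.sqrt(special.polygamma(1, shape)) / math.log(2)
    return (ic, mu - Z95 * sd)


# ---------------------------------------------------------------------------
# MGPS empirical Bayes


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the Poisson rate ratio lambda.

    Component i is Gamma(shape alpha_i, rate beta_i); ``weight`` is the
    mixing probability of component 1.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    weight: float
    loglik: float = math.nan

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValidationError("gamma hyperparameters must be positive")
        if not 0.0 <= self.weight <= 1.0:
            raise ValidationError("mixture weight must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return (self.weight * self.alpha1 / self.beta1
                + (1 - self.weight) * self.alpha2 / self.beta2)


class MgpsConvergenceError(RuntimeError):
    """Fit failed; carries the best parameters seen and diagnostics."""

    def __init__(self, message: str, best: MgpsPrior | None, diagnostics: dict):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics


# fixed multi-start points (shape1, rate1, shape2, rate2, weight): a diffuse
# classic start, one concentrated at lambda = 1, and a bimodal null+signal mix
_MGPS_STARTS = (
    (0.2, 0.1, 2.0, 4.0, 1 / 3),
    (20.0, 20.0, 2.0, 2.0, 0.9),
    (1.0, 1.0, 3.0, 0.3, 0.9),
)


def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    # marginal of Poisson(lambda*E) with lambda ~ Gamma(alpha, rate beta)
    return stats.nbinom.logpmf(a, alpha, beta / (beta + e))


def _mgps_negloglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    a1, b1, a2, b2 = np.exp(theta[:4])
    w = special.expit(theta[4])
    lp1 = _nb_logpmf(a, e, a1, b1) + np.log(w + 1e-300)
    lp2 = _nb_logpmf(a, e, a2, b2) + np.log(1 - w + 1e-300)
    return -float(np.sum(np.logaddexp(lp1, lp2)))


def fit_mgps_prior(
    cells: list[ContingencyCell],
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MgpsPrior:
    """Fit the mixture hyperparameters by marginal maximum likelihood.

    Deterministic: quasi-Newton optimisation from three fixed starting
    points; the best converged optimum wins.
    """
    if len(cells) < 2:
        raise ValidationError("MGPS prior fit needs at least 2 cells")
    a = np.array([c.a for c in cells], dtype=float)
    e = np.array([c.expected for c in cells], dtype=float)
    if np.any(e <= 0):
        # events absent from the data contribute no information
        keep = e > 0
        a, e = a[keep], e[keep]
    best: MgpsPrior | None = None
    diagnostics = {}
    for k, start in enumerate(_MGPS_STARTS):
        theta0 = np.array([*np.log(start[:4]), special.logit(start[4])])
        res = optimize.minimize(
            _mgps_negloglik, theta0, args=(a, e), method="L-BFGS-B",
            bounds=[(-12.0, 12.0)] * 5,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        diagnostics[f"start_{k}"] = {
            "success": bool(res.success), "neg_loglik": float(res.fun),
            "n_iter": int(res.nit),
        }
        if not np.isfinite(res.fun):
            continue
        a1, b1, a2, b2 = np.exp(res.x[:4])
        prior = MgpsPrior(
            alpha1=float(a1), beta1=float(b1), alpha2=float(a2),
            beta2=float(b2), weight=float(special.expit(res.x[4])),
            loglik=-float(res.fun),
        )
        if best is None or prior.loglik > best.loglik:
            best = prior
    if best is None:
        raise MgpsConvergenceError("MGPS fit did not converge", None, diagnostics)
    return best


def mgps_stats(cell: ContingencyCell, prior: MgpsPrior) -> tuple[float, float]:
    """EBGM (posterior geometric mean of lambda) and its 5th percentile.

    The posterior is again a two-gamma mixture with updated shapes/rates and
    a data-dependent weight; EBGM05 is root-found on the mixture CDF.
    """
    a, e = float(cell.a), float(cell.expected)
    if e <= 0:
        return (math.nan, math.nan)
    lw1 = math.log(prior.weight + 1e-300) + float(
        _nb_logpmf(np.array([a]), np.array([e]), prior.alpha1, prior.beta1)[0]
    )
    lw2 = math.log(1 - prior.weight + 1e-300) + float(
        _nb_logpmf(np.array([a]), np.array([e]), prior.alpha2, prior.beta2)[0]
    )
    norm = np.logaddexp(lw1, lw2)
    q1 = math.exp(lw1 - norm)
    shapes = (prior.alpha1 + a, prior.alpha2 + a)
    rates = (prior.beta1 + e, prior.beta2 + e)
    weights = (q1, 1.0 - q1)
    mean_log = sum(
        w * (special.digamma(s) - math.log(r))
        for w, s, r in zip(weights, shapes, rates)
    )
    ebgm = math.exp(mean_log)

    def mix_cdf(x: float) -> float:
        return sum(
            w * stats.gamma.cdf(x, s, scale=1 / r)
            for w, s, r in zip(weights, shapes, rates)
        )

    # the mixture 5% quantile is bracketed by the component 5% quantiles
    ppfs = [stats.gamma.ppf(0.05, s, scale=1 / r)
            for s, r in zip(shapes, rates)]
    lo, hi = min(ppfs), max(ppfs)
    if mix_cdf(lo) >= 0.05 or hi - lo < 1e-12:
        ebgm05 = lo
    elif mix_cdf(hi) <= 0.05:
        ebgm05 = hi
    else:
        ebgm05 = optimize.brentq(
            lambda x: mix_cdf(x) - 0.05, lo, hi, xtol=1e-6, rtol=1e-10,
        )
    return (ebgm, float(ebgm05))


# ---------------------------------------------------------------------------
# flags and tables


@dataclass(frozen=True)
class SignalResult:
    """All four statistics plus the per-algorithm and combined flags."""

    event: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    prr_chisq: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flag_ror: bool = False
    flag_prr: bool = False
    flag_bcpnn: bool = False
    flag_mgps: bool = False

    @property
    def n(self) -> int:
        return self.a

    @property
    def flag_positive(self) -> bool:
        return self.flag_ror and self.flag_prr and self.flag_bcpnn and self.flag_mgps


def compute_signal(
    cell: ContingencyCell,
    prior: MgpsPrior,
    thresholds: SignalThresholds = SignalThresholds(),
    zero_policy: str = "undefined",
    yates: bool = False,
) -> SignalResult:
    ror, lo, hi = ror_stats(cell, zero_policy)
    prr, chisq = prr_stats(cell, yates=yates, zero_policy=zero_policy)
    ic, ic025 = bcpnn_stats(cell)
    ebgm, ebgm05 = mgps_stats(cell, prior)
    draft = SignalResult(
        event=cell.event, a=cell.a, b=cell.b, c=cell.c, d=cell.d,
        ror=ror, ror_lo95=lo, ror_hi95=hi, prr=prr, prr_chisq=chisq,
        ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
    )
    return flag_signals(draft, thresholds)


def flag_signals(
    draft: SignalResult, thresholds: SignalThresholds = SignalThresholds()
) -> SignalResult:
    """Apply the per-algorithm positivity criteria.

    Undefined statistics (NaN) never satisfy a criterion.
    """
    t = thresholds
    return replace(
        draft,
        flag_ror=bool(
            draft.a >= t.min_count
            and np.isfinite(draft.ror_lo95)
            and draft.ror_lo95 > t.ror_lo95
        ),
        flag_prr=bool(
            draft.a >= t.min_count
            and np.isfinite(draft.prr) and draft.prr >= t.prr_min
            and np.isfinite(draft.prr_chisq) and draft.prr_chisq >= t.prr_chisq_min
        ),
        flag_bcpnn=bool(np.isfinite(draft.ic025) and draft.ic025 > t.ic025_min),
        flag_mgps=bool(np.isfinite(draft.ebgm05) and draft.ebgm05 > t.ebgm05_min),
    )


def signal_table(
    cells: list[ContingencyCell],
    thresholds: SignalThresholds = SignalThresholds(),
    zero_policy: str = "undefined",
    yates: bool = False,
    prior: MgpsPrior | None = None,
) -> pd.DataFrame:
    """Compute all statistics for a set of cells into a tidy frame.

    The MGPS prior is fitted across all supplied cells unless given.
    """
    if prior is None:
        prior = fit_mgps_prior(cells)
    rows = [
        compute_signal(cell, prior, thresholds, zero_policy, yates)
        for cell in cells
    ]
    frame = pd.DataFrame([
        {
            "event": r.event, "n": r.a, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "ror": r.ror, "ror_lo95": r.ror_lo95, "ror_hi95": r.ror_hi95,
            "prr": r.prr, "prr_chisq": r.prr_chisq,
            "ic": r.ic, "ic025": r.ic025, "ebgm": r.ebgm, "ebgm05": r.ebgm05,
            "flag_ror": r.flag_ror, "flag_prr": r.flag_prr,
            "flag_bcpnn": r.flag_bcpnn, "flag_mgps": r.flag_mgps,
            "flag_positive": r.flag_positive,
        }
        for r in rows
    ])
    return frame.sort_values("event", kind="mergesort").reset_index(drop=True)


_RANK_KEYS = {"n": "n", "ror": "ror", "ebgm": "ebgm"}


def rank_signals(results: pd.DataFrame, by: str = "n") -> pd.DataFrame:
    """Stable descending sort with lexicographic event tie-break."""
    if by not in _RANK_KEYS:
        raise ValidationError(
            f"unknown sort key {by!r}; choose one of {sorted(_RANK_KEYS)}"
        )
    if results.empty:
        return results.copy()
    col = _RANK_KEYS[by]
    return (
        results.sort_values(
            [col, "event"], ascending=[False, True], kind="mergesort",
            na_position="last",
        ).reset_index(drop=True)
    )
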