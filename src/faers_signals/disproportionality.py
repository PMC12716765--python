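"""The four disproportionality statistics and the joint signal criteria.

For one drug–event pair the 2×2 contingency table over a deduplicated
spontaneous-reporting database is

    =================  ==========  =========
                       target AE   other AEs
    =================  ==========  =========
    target drug        a           b
    other drugs        c           d
    =================  ==========  =========

with N = a+b+c+d. The four screening statistics are

* ROR  = ad/bc, with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
* PRR  = a(c+d) / (c(a+b)), with the 2×2 chi-squared
  χ² = (ad−bc)²·N / ((a+b)(c+d)(a+c)(b+d));
* BCPNN information component IC = log₂[aN / ((a+c)(a+b))], the log₂
  observed-to-expected reporting ratio, with IC025 = E(IC) − 2·√V(IC) from the
  closed-form Bayesian posterior (see :func:`bcpnn_ic`);
* EBGM = aN / ((a+c)(a+b)) — the same observed-to-expected ratio on the
  natural scale, reported without gamma-mixture shrinkage — with
  EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d)).

Hence IC = log₂(EBGM) identically whenever both are defined.

A pair is a *signal* when it passes all four tests jointly: ROR lower 95%
bound > 1 with a ≥ 3; PRR ≥ 2 with χ² ≥ 4; IC025 > 0; EBGM05 > 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortCounts

NAN = float("nan")


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts a/b/c/d of the drug–event 2×2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")
        if self.n == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def continuity_corrected(self, k: float = 0.5) -> "ContingencyTableF":
        return ContingencyTableF(self.a + k, self.b + k, self.c + k, self.d + k)


@dataclass(frozen=True)
class ContingencyTableF:
    """Real-valued table produced by the Haldane–Anscombe +0.5 correction."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class SignalEstimate:
    """The four statistics with their lower/upper bounds for one pair.

    Undefined values (zero cells under the default policy) are NaN with
    ``zero_cell_policy_applied`` set.
    """

    ror: float = NAN
    ror_lo95: float = NAN
    ror_hi95: float = NAN
    prr: float = NAN
    chi2: float = NAN
    ic: float = NAN
    ic025: float = NAN
    ebgm: float = NAN
    ebgm05: float = NAN
    zero_cell_policy_applied: bool = False


@dataclass(frozen=True)
class CriteriaDecision:
    ror_pass: bool
    prr_pass: bool
    bcpnn_pass: bool
    mgps_pass: bool

    @property
    def all_four(self) -> bool:
        return self.ror_pass and self.prr_pass and self.bcpnn_pass and self.mgps_pass


ZeroCellPolicy = Literal["undefined", "haldane"]


@dataclass(frozen=True)
class Thresholds:
    """Joint significance thresholds.

    ``strict=False`` (default) uses the inclusive boundaries PRR ≥ 2, χ² ≥ 4,
    a ≥ 3; ``strict=True`` the strict variants PRR > 2, χ² > 4, a > 3. The
    ROR, IC025 and EBGM05 bounds are strict in both modes.
    """

    min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0
    strict: bool = False


def build_table(
    a: int, n_target: int, event_background: int, n_background: int
) -> ContingencyTable:
    """Assemble the 2×2 table from cohort margins (b and d by subtraction)."""
    if a > n_target or event_background > n_background:
        raise ValueError(
            f"inconsistent margins: a={a} n_target={n_target} "
            f"c={event_background} n_background={n_background}"
        )
    return ContingencyTable(a, n_target - a, event_background, n_background - event_background)


def _wald_halfwidth(t) -> float:
    return 1.96 * math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def ror(t: ContingencyTable | ContingencyTableF) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI; (nan, nan, nan) on a zero cell."""
    if t.has_zero_cell:
        return NAN, NAN, NAN
    est = (t.a * t.d) / (t.b * t.c)
    hw = _wald_halfwidth(t)
    return est, math.exp(math.log(est) - hw), math.exp(math.log(est) + hw)


def prr_chi2(t: ContingencyTable | ContingencyTableF) -> tuple[float, float]:
    """Proportional reporting ratio and the (uncorrected) 2×2 chi-squared."""
    prr_denom = t.c * (t.a + t.b)
    p = (t.a * (t.c + t.d)) / prr_denom if prr_denom > 0 else NAN
    chi_denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    chi = ((t.a * t.d - t.b * t.c) ** 2 * t.n) / chi_denom if chi_denom > 0 else NAN
    return p, chi


def observed_expected_ratio(t: ContingencyTable | ContingencyTableF) -> float:
    """a·N / ((a+c)(a+b)) — the unshrunk observed/expected reporting ratio."""
    denom = (t.a + t.c) * (t.a + t.b)
    if denom == 0:
        return NAN
    return (t.a * t.n) / denom


def bcpnn_ic(
    t: ContingencyTable | ContingencyTableF,
    method: Literal["closed_form", "mc"] = "closed_form",
    mc_draws: int = 20000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Information component and its lower bound IC025.

    The point estimate is the unshrunk IC = log₂[aN/((a+c)(a+b))]; it is NaN
    when a = 0 (log of zero).

    ``closed_form`` (default) computes IC025 = E(IC) − 2·√V(IC) from the
    original BCPNN beta-binomial posterior with unit prior parameters
    (alpha1 = beta1 = gamma11 = 1, alpha = beta = 2):

        gamma  = gamma11 * (N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1))
        E(IC)  = log2[ (a+gamma11)(N+alpha)(N+beta)
                       / ((N+gamma)(a+b+alpha1)(a+c+beta1)) ]
        V(IC)  = (1/ln2)^2 * [ (N-a+gamma-gamma11) / ((a+gamma11)(1+N+gamma))
                             + (N-(a+b)+alpha-alpha1) / ((a+b+alpha1)(1+N+alpha))
                             + (N-(a+c)+beta-beta1)   / ((a+c+beta1)(1+N+beta)) ]

    ``mc`` instead draws the cell probabilities from a Dirichlet(a+1, b+1,
    c+1, d+1) posterior and takes the empirical 2.5% quantile of the sampled
    IC values.
    """
    oe = observed_expected_ratio(t)
    ic = math.log2(oe) if oe > 0 else NAN

    if method == "mc":
        rng = rng or np.random.default_rng(0)
        p = rng.dirichlet(np.asarray([t.a, t.b, t.c, t.d], dtype=float) + 1.0, size=mc_draws)
        ic_draws = np.log2(p[:, 0] / ((p[:, 0] + p[:, 1]) * (p[:, 0] + p[:, 2])))
        return ic, float(np.quantile(ic_draws, 0.025))

    a, n1, n2, n = t.a, t.a + t.b, t.a + t.c, t.n
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((n1 + alpha1) * (n2 + beta1))
    e_ic = math.log2(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (n1 + alpha1) * (n2 + beta1))
    )
    v_ic = (1 / math.log(2)) ** 2 * (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - n1 + alpha - alpha1) / ((n1 + alpha1) * (1 + n + alpha))
        + (n - n2 + beta - beta1) / ((n2 + beta1) * (1 + n + beta))
    )
    return ic, e_ic - 2.0 * math.sqrt(v_ic)


def mgps_ebgm(t: ContingencyTable | ContingencyTableF) -> tuple[float, float]:
    """Unshrunk EBGM = aN/((a+c)(a+b)) and its Wald-style lower bound.

    EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d)); NaN on a zero cell.
    """
    est = observed_expected_ratio(t)
    if t.has_zero_cell or not est > 0:
        return (est if est > 0 else NAN), NAN
    return est, math.exp(math.log(est) - _wald_halfwidth(t))


def compute_estimate(
    t: ContingencyTable,
    zero_cell_policy: ZeroCellPolicy = "undefined",
    ic_method: Literal["closed_form", "mc"] = "closed_form",
    rng: np.random.Generator | None = None,
) -> SignalEstimate:
    """All four statistics for one table under the chosen zero-cell policy."""
    flagged = t.has_zero_cell
    if flagged and zero_cell_policy == "haldane":
        tt: ContingencyTable | ContingencyTableF = t.continuity_corrected()
    else:
        tt = t
    r, lo, hi = ror(tt)
    p, chi = prr_chi2(tt)
    ic, ic025 = bcpnn_ic(tt, method=ic_method, rng=rng)
    eb, eb05 = mgps_ebgm(tt)
    return SignalEstimate(
        ror=r, ror_lo95=lo, ror_hi95=hi,
        prr=p, chi2=chi,
        ic=ic, ic025=ic025,
        ebgm=eb, ebgm05=eb05,
        zero_cell_policy_applied=flagged,
    )


def evaluate_criteria(
    e: SignalEstimate, a: int, thresholds: Thresholds | None = None
) -> CriteriaDecision:
    """Per-algorithm pass flags and the joint all-four verdict.

    A NaN (undefined) statistic fails its test.
    """
    th = thresholds or Thresholds()

    def ge(x: float, bound: float) -> bool:
        # inclusive by default; strict mode turns >= into >
        return (x > bound) if th.strict else (x >= bound)

    a_ok = (a > th.min_a) if th.strict else (a >= th.min_a)
    ror_pass = bool(e.ror_lo95 > 1.0) and a_ok
    prr_pass = bool(ge(e.prr, th.prr_min)) and bool(ge(e.chi2, th.chi2_min))
    bcpnn_pass = bool(e.ic025 > th.ic025_min)
    mgps_pass = bool(e.ebgm05 > th.ebgm05_min)
    return CriteriaDecision(ror_pass, prr_pass, bcpnn_pass, mgps_pass)


@dataclass(frozen=True)
class ScreenRow:
    term: str
    level: str
    table: ContingencyTable
    estimate: SignalEstimate
    decision: CriteriaDecision


def screen(
    counts: CohortCounts,
    level: str = "PT",
    min_a: int = 1,
    thresholds: Thresholds | None = None,
    zero_cell_policy: ZeroCellPolicy = "undefined",
    ic_method: Literal["closed_form", "mc"] = "closed_form",
    rng: np.random.Generator | None = None,
) -> list[ScreenRow]:
    """One scored row per term with a ≥ ``min_a``, ordered by descending a
    then term name (deterministic). Top-k views are just slices."""
    target_counts, background_counts = counts.at_level(level)
    rows = []
    for term, a in target_counts.items():
        if a < min_a:
            continue
        t = build_table(
            a,
            counts.n_target_cases,
            background_counts.get(term, 0),
            counts.n_background_cases,
        )
        est = compute_estimate(t, zero_cell_policy, ic_method, rng)
        dec = evaluate_criteria(est, a, thresholds)
        rows.append(ScreenRow(term, level.upper(), t, est, dec))
    rows.sort(key=lambda r: (-r.table.a, r.term))
    return rows


SCREEN_COLUMNS = [
    "term", "level", "a", "b", "c", "d",
    "ROR", "ROR_lo95", "ROR_hi95", "PRR", "chi2",
    "IC", "IC025", "EBGM", "EBGM05",
    "ror_pass", "prr_pass", "bcpnn_pass", "mgps_pass", "all_four",
]


def screen_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Screen results as a flat table mirroring the published column layout."""
    recs = []
    for r in rows:
        recs.append({
            "term": r.term, "level": r.level,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "ROR": r.estimate.ror, "ROR_lo95": r.estimate.ror_lo95,
            "ROR_hi95": r.estimate.ror_hi95,
            "PRR": r.estimate.prr, "chi2": r.estimate.chi2,
            "IC": r.estimate.ic, "IC025": r.estimate.ic025,
            "EBGM": r.estimate.ebgm, "EBGM05": r.estimate.ebgm05,
            "ror_pass": r.decision.ror_pass, "prr_pass": r.decision.prr_pass,
            "bcpnn_pass": r.decision.bcpnn_pass, "mgps_pass": r.decision.mgps_pass,
            "all_four": r.decision.all_four,
        })
    return pd.DataFrame.from_records(recs, columns=SCREEN_COLUMNS)
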