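"""The four disproportionality statistics, their bounds, and the joint rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faers_signals.cohort import CohortCounts
from faers_signals.disproportionality import (
    ContingencyTable,
    SignalEstimate,
    Thresholds,
    bcpnn_ic,
    build_table,
    compute_estimate,
    evaluate_criteria,
    mgps_ebgm,
    prr_chi2,
    ror,
    screen,
    screen_frame,
)

from _oracles import chi2_oracle, ebgm_oracle, ic_oracle, prr_oracle, ror_oracle


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------


def test_build_table_by_subtraction():
    t = build_table(5, 100, 100, 10000)
    assert (t.a, t.b, t.c, t.d) == (5, 95, 100, 9900)


def test_build_table_zero_margins():
    t = build_table(0, 10, 0, 10)
    assert (t.a, t.b, t.c, t.d) == (0, 10, 0, 10)


def test_build_table_inconsistent_margins_fatal():
    with pytest.raises(ValueError):
        build_table(11, 10, 0, 10)
    with pytest.raises(ValueError):
        ContingencyTable(-1, 1, 1, 1)


# ---------------------------------------------------------------------------
# point values frozen from the independent oracle
# ---------------------------------------------------------------------------

T = ContingencyTable(5, 95, 100, 9900)


def test_symmetric_table_is_null():
    t = ContingencyTable(10, 10, 10, 10)
    r, lo, hi = ror(t)
    assert r == pytest.approx(1.0)
    assert lo < 1.0 < hi
    p, chi = prr_chi2(t)
    assert (p, chi) == (1.0, 0.0)
    ic, ic025 = bcpnn_ic(t)
    assert ic == pytest.approx(0.0)
    assert ic025 < 0.0
    eb, _ = mgps_ebgm(t)
    assert eb == pytest.approx(1.0)


def test_ror_point_and_interval():
    r, lo, hi = ror(T)
    assert r == pytest.approx(5.210526315789474, rel=1e-12)   # 49500/9500
    assert lo == pytest.approx(2.0752, abs=2e-4)
    assert hi == pytest.approx(13.0815, abs=2e-3)


def test_prr_and_chi2_point_values():
    p, chi = prr_chi2(T)
    assert p == pytest.approx(5.0, rel=1e-12)                  # 5*10000/(100*100)
    assert chi == pytest.approx(15.39824, abs=1e-4)


def test_ic_and_ebgm_point_values():
    eb, _ = mgps_ebgm(T)
    assert eb == pytest.approx(4.80952380952, rel=1e-10)       # 5*10100/(105*100)
    ic, _ = bcpnn_ic(T)
    assert ic == pytest.approx(math.log2(4.80952380952), rel=1e-10)  # 2.2659


def test_ic025_is_below_ic_and_sane():
    ic, ic025 = bcpnn_ic(T)
    assert ic025 < ic
    # large clear signal has a positive lower bound
    big = ContingencyTable(150, 2804, 5000, 500000)
    _, ic025_big = bcpnn_ic(big)
    assert ic025_big > 0


def test_mc_ic025_close_to_closed_form_at_large_counts():
    # the Bayesian prior's shrinkage vanishes for large cells, where the
    # Dirichlet-quantile and closed-form bounds must agree
    big = ContingencyTable(500, 9500, 20000, 970000)
    rng = np.random.default_rng(5)
    ic, cf = bcpnn_ic(big)
    _, mc = bcpnn_ic(big, method="mc", mc_draws=40000, rng=rng)
    assert mc == pytest.approx(cf, abs=0.05)
    assert mc < ic


def test_mc_ic025_below_point_estimate_at_small_counts():
    rng = np.random.default_rng(5)
    ic, mc = bcpnn_ic(T, method="mc", mc_draws=20000, rng=rng)
    assert mc < ic


# ---------------------------------------------------------------------------
# oracle equivalence + invariants on random tables
# ---------------------------------------------------------------------------


def test_all_four_match_bruteforce_oracle_on_random_tables():
    rng = np.random.default_rng(1234)
    cells = rng.integers(1, 10**6, size=(1000, 4))
    for row in cells:
        a, b, c, d = (int(x) for x in row)  # exact big-int arithmetic in oracle
        t = ContingencyTable(a, b, c, d)
        r, lo, hi = ror(t)
        orc = ror_oracle(a, b, c, d)
        assert r == pytest.approx(orc[0], rel=1e-10)
        assert lo == pytest.approx(orc[1], rel=1e-10)
        assert hi == pytest.approx(orc[2], rel=1e-10)
        p, chi = prr_chi2(t)
        assert p == pytest.approx(prr_oracle(a, b, c, d), rel=1e-10)
        assert chi == pytest.approx(chi2_oracle(a, b, c, d), rel=1e-10)
        eb, eb05 = mgps_ebgm(t)
        oeb, oeb05 = ebgm_oracle(a, b, c, d)
        assert eb == pytest.approx(oeb, rel=1e-10)
        assert eb05 == pytest.approx(oeb05, rel=1e-10)
        ic, _ = bcpnn_ic(t)
        assert ic == pytest.approx(ic_oracle(a, b, c, d), rel=1e-10)
        # the log2 identity linking the two Bayesian statistics
        assert ic == pytest.approx(math.log2(eb), abs=1e-12)


@settings(max_examples=200, deadline=None)
@given(st.integers(1, 10**5), st.integers(1, 10**5),
       st.integers(1, 10**5), st.integers(1, 10**5))
def test_interval_orderings(a, b, c, d):
    e = compute_estimate(ContingencyTable(a, b, c, d))
    assert e.ror_lo95 <= e.ror <= e.ror_hi95
    assert e.ebgm05 <= e.ebgm
    assert e.ic025 <= e.ic
    assert e.chi2 >= 0


def test_monotonicity_in_a():
    base = ContingencyTable(10, 500, 300, 50000)
    prev = compute_estimate(base)
    for a in (11, 20, 50):
        cur = compute_estimate(ContingencyTable(a, 500, 300, 50000))
        assert cur.ror > prev.ror
        assert cur.prr > prev.prr
        assert cur.ebgm > prev.ebgm
        assert cur.ic > prev.ic
        prev = cur


# ---------------------------------------------------------------------------
# zero cells
# ---------------------------------------------------------------------------


def test_zero_cell_default_policy_is_undefined():
    e = compute_estimate(ContingencyTable(0, 10, 5, 100))
    assert math.isnan(e.ror) and math.isnan(e.ic) and math.isnan(e.ebgm05)
    assert e.zero_cell_policy_applied
    d = evaluate_criteria(e, 0)
    assert not (d.ror_pass or d.prr_pass or d.bcpnn_pass or d.mgps_pass)
    assert not d.all_four


def test_zero_cell_haldane_policy_defines_everything():
    e = compute_estimate(ContingencyTable(0, 10, 5, 100), zero_cell_policy="haldane")
    assert e.zero_cell_policy_applied
    assert not math.isnan(e.ror) and not math.isnan(e.ebgm05)
    # +0.5 on all cells: ROR = (0.5*100.5)/(10.5*5.5)
    assert e.ror == pytest.approx(0.5 * 100.5 / (10.5 * 5.5), rel=1e-12)


# ---------------------------------------------------------------------------
# joint criteria
# ---------------------------------------------------------------------------


def test_boundary_ror_lower_bound_exactly_one_fails():
    e = SignalEstimate(ror=2.0, ror_lo95=1.0, ror_hi95=4.0, prr=5, chi2=10,
                       ic=1, ic025=0.5, ebgm=5, ebgm05=3)
    assert not evaluate_criteria(e, 10).ror_pass


def test_inclusive_vs_strict_boundaries():
    e = SignalEstimate(ror=3, ror_lo95=1.5, ror_hi95=6, prr=2.0, chi2=4.0,
                       ic=1, ic025=0.5, ebgm=5, ebgm05=3)
    lenient = evaluate_criteria(e, 3)
    assert lenient.prr_pass and lenient.ror_pass and lenient.all_four
    strict = evaluate_criteria(e, 3, Thresholds(strict=True))
    assert not strict.prr_pass and not strict.ror_pass


def test_published_signal_row_passes_all_four():
    # a high-frequency suicide-attempt signal: a=150, ROR lower bound 13.02,
    # PRR 15.08 with chi2 1968.5, IC025 3.67, EBGM05 13.14
    e = SignalEstimate(ror=15.3, ror_lo95=13.02, ror_hi95=17.98,
                       prr=15.08, chi2=1968.5, ic=3.91, ic025=3.67,
                       ebgm=15.04, ebgm05=13.14)
    assert evaluate_criteria(e, 150).all_four


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def _counts(target_counts, background_counts, n_t, n_b):
    return CohortCounts(
        n_target_cases=n_t, n_background_cases=n_b,
        target_pt_counts=target_counts, background_pt_counts=background_counts,
    )


def test_screen_single_term():
    rows = screen(_counts({"PT_X": 5}, {"PT_X": 100}, 100, 10000))
    assert len(rows) == 1
    assert rows[0].term == "PT_X"
    assert rows[0].estimate.ror == pytest.approx(5.2105, abs=1e-3)


def test_screen_ordering_and_min_a():
    counts = _counts({"B": 10, "A": 10, "C": 3, "D": 1},
                     {"B": 5, "A": 5, "C": 5, "D": 5}, 50, 5000)
    rows = screen(counts, min_a=3)
    assert [r.term for r in rows] == ["A", "B", "C"]  # desc a, then name
    frame = screen_frame(rows)
    assert list(frame["term"]) == ["A", "B", "C"]
    assert set(frame.columns) >= {"ROR", "PRR", "chi2", "IC", "EBGM05", "all_four"}
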