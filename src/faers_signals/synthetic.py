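"""Synthetic FAERS-style bundle generator with planted ground truth.

The generator emulates the structural features of a spontaneous-reporting
quarter that the pipeline must survive — heavy-tailed PT reporting marginals,
a target drug taken by a share of cases, duplicate case versions, partial
dates, and missing demographics — while recording exact ground truth (planted
drug–event rate ratios, realized contingency cells, duplicate CASEIDs, and the
full per-case truth) so every pipeline stage can be checked against what was
planted.

Model: each case independently includes PT *j* with probability ``p_j``
proportional to a power-law weight (scaled to a configurable mean number of
PTs per case). A fraction of cases take the target drug as primary suspect;
for those cases a planted signal (pt, rho) multiplies the inclusion
probability of that PT by rho (capped at 0.99; a rho pushing the probability
past the cap is rejected as infeasible). All other PTs are reported at
background rates, so unplanted PTs have true rate ratio 1 by construction.

Onset times follow a two-component mixture: an early exponential component
(acute reactions within days–weeks of therapy start) and a late component
offset beyond one year (delayed toxicity), matching the bimodal onset pattern
spontaneous reports show for many drugs.

Determinism: one pseudo-random stream per concern, split from the master seed
via ``numpy.random.SeedSequence.spawn``, so adding a field never perturbs
earlier draws; an identical config yields byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np

from .faers_io import (
    DrugEntry,
    PartialDate,
    RawBundle,
    ReportCase,
    ReportKey,
)

PROB_CAP = 0.99

_STREAMS = (
    "assign", "reactions", "demo", "dates", "outcomes", "duplicates", "drugs", "spare",
)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; the defaults are the study conditions used
    throughout the tests and the acceptance run."""

    seed: int
    n_cases: int = 5000
    n_drugs: int = 50
    n_pts: int = 200
    power_law_exponent: float = 1.1
    mean_pts_per_case: float = 3.0
    target_drug: str = "DRUG_TARGET"
    target_drug_share: float = 0.1
    planted_signals: tuple[tuple[str, float], ...] = ()
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.05
    missing_demo_rate: float = 0.2
    # (fraction_early, early_mean_days, late_mean_days); the late component is
    # offset to start at day 360.
    onset_mixture: tuple[float, float, float] = (0.8, 8.0, 120.0)
    concomitant_rate: float = 0.3
    nonps_target_rate: float = 0.05  # background cases listing the target as C

    def __post_init__(self):
        for name in ("target_drug_share", "duplicate_rate", "partial_date_rate",
                     "missing_demo_rate", "concomitant_rate", "nonps_target_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(rho <= 0 for _, rho in self.planted_signals):
            raise ValueError("planted rate ratios must be > 0")
        frac, early, late = self.onset_mixture
        if not 0.0 <= frac <= 1.0 or early <= 0 or late <= 0:
            raise ValueError(f"invalid onset_mixture {self.onset_mixture}")

    def pt_name(self, j: int) -> str:
        return f"PT_{j:04d}"

    def drug_name(self, j: int) -> str:
        return f"DRUG_{j:03d}"


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated bundle."""

    config: SimConfig
    true_rr: dict[str, float]
    expected_tables: dict[str, tuple[float, float, float, float]]
    realized_tables: dict[str, tuple[int, int, int, int]]
    duplicate_caseids: set[int]
    n_target_cases: int
    n_background_cases: int
    cases: list[ReportCase] = field(default_factory=list)
    tto_days: dict[int, int] = field(default_factory=dict)  # caseid -> planted onset


def _base_probabilities(cfg: SimConfig) -> np.ndarray:
    w = (np.arange(1, cfg.n_pts + 1, dtype=float)) ** (-cfg.power_law_exponent)
    p = w / w.sum() * cfg.mean_pts_per_case
    return np.minimum(p, PROB_CAP)


def _target_probabilities(cfg: SimConfig, p: np.ndarray) -> np.ndarray:
    pt_index = {cfg.pt_name(j): j for j in range(cfg.n_pts)}
    p_t = p.copy()
    for pt, rho in cfg.planted_signals:
        j = pt_index.get(pt.upper())
        if j is None:
            raise ValueError(f"planted signal names unknown PT {pt!r}")
        boosted = rho * p[j]
        if boosted > PROB_CAP:
            raise ValueError(
                f"infeasible planted signal ({pt}, rho={rho}): inclusion "
                f"probability {boosted:.3f} exceeds cap {PROB_CAP}"
            )
        p_t[j] = boosted
    return p_t


def _format_date(d: date, precision: str) -> str:
    if precision == "day":
        return f"{d.year:04d}{d.month:02d}{d.day:02d}"
    if precision == "month":
        return f"{d.year:04d}{d.month:02d}"
    return f"{d.year:04d}"


def generate(cfg: SimConfig) -> tuple[RawBundle, SyntheticTruth]:
    """Generate one in-memory bundle plus its ground truth."""
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS)))
    }
    n = cfg.n_cases
    p = _base_probabilities(cfg)
    p_t = _target_probabilities(cfg, p)

    is_target = rngs["assign"].random(n) < cfg.target_drug_share
    u = rngs["reactions"].random((n, cfg.n_pts))
    probs = np.where(is_target[:, None], p_t[None, :], p[None, :])
    include = u < probs

    # --- demographics ------------------------------------------------------
    rd = rngs["demo"]
    sex_draw = rd.random(n)
    ages = np.clip(rd.normal(55.0, 20.0, size=n), 1.0, 100.0)
    age_is_dec = rd.random(n) < 0.1
    weights_kg = np.clip(rd.normal(72.0, 15.0, size=n), 35.0, 150.0)
    wt_is_lbs = rd.random(n) < 0.2
    miss_age = rd.random(n) < cfg.missing_demo_rate
    miss_wt = rd.random(n) < cfg.missing_demo_rate
    miss_sex = rd.random(n) < cfg.missing_demo_rate
    occ_codes = np.array(["MD", "CN", "OT", "PH", "HP", "LW"])
    occ = occ_codes[rd.choice(len(occ_codes), size=n,
                              p=[0.35, 0.32, 0.15, 0.07, 0.07, 0.04])]
    miss_occ = rd.random(n) < cfg.missing_demo_rate
    countries = np.array(["US", "CH", "FR", "JP", "CA", "GB", "DE"])
    country = countries[rd.choice(len(countries), size=n,
                                  p=[0.5, 0.1, 0.08, 0.08, 0.06, 0.09, 0.09])]
    miss_country = rd.random(n) < cfg.missing_demo_rate

    # --- dates and onset ---------------------------------------------------
    rt = rngs["dates"]
    frac_early, early_mean, late_mean = cfg.onset_mixture
    early = rt.random(n) < frac_early
    tto = np.where(
        early,
        rt.exponential(early_mean, size=n),
        360.0 + rt.exponential(late_mean, size=n),
    ).astype(int)
    start_epoch = date(2004, 1, 1).toordinal()
    start_span = date(2023, 12, 31).toordinal() - start_epoch
    start_ord = start_epoch + rt.integers(0, start_span, size=n)
    event_ord = start_ord + tto
    fda_ord = event_ord + rt.integers(0, 61, size=n)
    partial_event = rt.random(n) < cfg.partial_date_rate
    partial_start = rt.random(n) < cfg.partial_date_rate
    partial_kind = np.where(rt.random(n) < 0.5, "month", "year")

    # --- outcomes ----------------------------------------------------------
    ro = rngs["outcomes"]
    has_outcome = ro.random(n) >= 0.3
    outc_pool = np.array(["HO", "OT", "DE", "LT", "DS", "CA", "RI"])
    outc = outc_pool[ro.choice(len(outc_pool), size=n,
                               p=[0.33, 0.3, 0.14, 0.06, 0.08, 0.04, 0.05])]

    # --- drugs -------------------------------------------------------------
    rdr = rngs["drugs"]
    other_ps = rdr.integers(0, cfg.n_drugs, size=n)
    has_conc = rdr.random(n) < cfg.concomitant_rate
    conc_drug = rdr.integers(0, cfg.n_drugs, size=n)
    bg_lists_target = rdr.random(n) < cfg.nonps_target_rate

    # --- duplicates --------------------------------------------------------
    rdup = rngs["duplicates"]
    is_dup = rdup.random(n) < cfg.duplicate_rate
    dup_gap = rdup.integers(1, 31, size=n)  # days earlier for the stale version

    demo_rows: list[dict[str, str]] = []
    drug_rows: list[dict[str, str]] = []
    reac_rows: list[dict[str, str]] = []
    ther_rows: list[dict[str, str]] = []
    outc_rows: list[dict[str, str]] = []
    truth_cases: list[ReportCase] = []
    tto_truth: dict[int, int] = {}
    duplicate_caseids: set[int] = set()

    for i in range(n):
        caseid = 10_000_000 + i
        pts = [cfg.pt_name(j) for j in np.nonzero(include[i])[0]]

        sex_code = "" if miss_sex[i] else ("F" if sex_draw[i] < 0.55 else "M")
        if miss_age[i]:
            age_val, age_cod, true_age = "", "", None
        elif age_is_dec[i]:
            dec = max(1, int(ages[i]) // 10)
            age_val, age_cod, true_age = str(dec), "DEC", dec * 10.0
        else:
            yr = int(round(ages[i]))
            age_val, age_cod, true_age = str(yr), "YR", float(yr)
        if miss_wt[i]:
            wt_val, wt_cod, true_wt = "", "", None
        elif wt_is_lbs[i]:
            lbs = round(weights_kg[i] / 0.453592, 1)
            wt_val, wt_cod, true_wt = str(lbs), "LBS", lbs * 0.453592
        else:
            kg = round(float(weights_kg[i]), 1)
            wt_val, wt_cod, true_wt = str(kg), "KG", kg
        occ_code = "" if miss_occ[i] else str(occ[i])
        ctry = "" if miss_country[i] else str(country[i])

        start_d = date.fromordinal(int(start_ord[i]))
        event_d = date.fromordinal(int(event_ord[i]))
        fda_d = date.fromordinal(int(fda_ord[i]))
        ev_precision = partial_kind[i] if partial_event[i] else "day"
        st_precision = partial_kind[i] if partial_start[i] else "day"
        event_str = _format_date(event_d, ev_precision)
        start_str = _format_date(start_d, st_precision)
        fda_str = _format_date(fda_d, "day")

        # version numbering: stale duplicate (if any) is version 1, the
        # current report version 2; singletons are version 1.
        final_version = 2 if is_dup[i] else 1
        final_pid = caseid * 10 + final_version

        drugs_for_case: list[tuple[str, str, str]] = []  # (name, role, start)
        if is_target[i]:
            drugs_for_case.append((cfg.target_drug, "PS", start_str))
            if has_conc[i]:
                drugs_for_case.append((cfg.drug_name(int(conc_drug[i])), "C", ""))
        else:
            drugs_for_case.append((cfg.drug_name(int(other_ps[i])), "PS", start_str))
            if bg_lists_target[i]:
                drugs_for_case.append((cfg.target_drug, "C", ""))
            elif has_conc[i]:
                drugs_for_case.append((cfg.drug_name(int(conc_drug[i])), "C", ""))

        outcomes = frozenset({str(outc[i])}) if has_outcome[i] else frozenset()

        def emit(pid: int, fda: str, pt_list: list[str]) -> None:
            demo_rows.append({
                "primaryid": str(pid), "caseid": str(caseid), "fda_dt": fda,
                "event_dt": event_str, "age": age_val, "age_cod": age_cod,
                "sex": sex_code, "wt": wt_val, "wt_cod": wt_cod,
                "occp_cod": occ_code, "occr_country": ctry,
                "reporter_country": ctry,
            })
            for seq, (name, role, start) in enumerate(drugs_for_case, start=1):
                drug_rows.append({
                    "primaryid": str(pid), "caseid": str(caseid),
                    "drug_seq": str(seq), "role_cod": role, "drugname": name,
                })
                if start:
                    ther_rows.append({
                        "primaryid": str(pid), "caseid": str(caseid),
                        "dsg_drug_seq": str(seq), "start_dt": start, "end_dt": "",
                    })
            for pt in pt_list:
                reac_rows.append({
                    "primaryid": str(pid), "caseid": str(caseid), "pt": pt,
                })
            if has_outcome[i]:
                outc_rows.append({
                    "primaryid": str(pid), "caseid": str(caseid),
                    "outc_cod": str(outc[i]),
                })

        if is_dup[i]:
            duplicate_caseids.add(caseid)
            stale_fda = date.fromordinal(int(fda_ord[i]) - int(dup_gap[i]))
            # the stale version may lack the last-reported reaction
            stale_pts = pts[:-1] if len(pts) > 1 else pts
            emit(caseid * 10 + 1, _format_date(stale_fda, "day"), stale_pts)
        emit(final_pid, fda_str, pts)

        truth_cases.append(ReportCase(
            key=ReportKey(final_pid, caseid, PartialDate.from_date(fda_d)),
            sex={"F": "female", "M": "male"}.get(sex_code, "unknown"),
            age_years=true_age,
            weight_kg=true_wt,
            reporter_occupation={
                "MD": "physician", "CN": "consumer", "OT": "other_health_professional",
                "PH": "pharmacist", "HP": "health_professional", "LW": "lawyer",
            }.get(occ_code, "missing"),
            country=ctry or None,
            drugs=[
                DrugEntry(name, role, PartialDate.parse(start) if start else None)
                for name, role, start in drugs_for_case
            ],
            reactions=frozenset(pts),
            outcomes=outcomes,
            event_date=PartialDate.parse(event_str),
        ))
        if is_target[i] and ev_precision == "day" and st_precision == "day":
            tto_truth[caseid] = int(tto[i])

    # --- truth tables ------------------------------------------------------
    n_target = int(is_target.sum())
    n_background = n - n_target
    true_rr = {cfg.pt_name(j): 1.0 for j in range(cfg.n_pts)}
    for pt, rho in cfg.planted_signals:
        true_rr[pt.upper()] = float(rho)
    realized: dict[str, tuple[int, int, int, int]] = {}
    expected: dict[str, tuple[float, float, float, float]] = {}
    a_real = include[is_target].sum(axis=0)
    c_real = include[~is_target].sum(axis=0)
    exp_nt = n * cfg.target_drug_share
    exp_nb = n * (1 - cfg.target_drug_share)
    for j in range(cfg.n_pts):
        name = cfg.pt_name(j)
        a, c = int(a_real[j]), int(c_real[j])
        realized[name] = (a, n_target - a, c, n_background - c)
        ea, ec = exp_nt * p_t[j], exp_nb * p[j]
        expected[name] = (ea, exp_nt - ea, ec, exp_nb - ec)

    bundle = RawBundle(quarter_id=f"SYNTH-{cfg.seed}")
    bundle.tables = {
        "DEMO": demo_rows, "DRUG": drug_rows, "REAC": reac_rows,
        "THER": ther_rows, "OUTC": outc_rows,
    }
    # normalise row keys to uppercase, matching what read_bundle produces
    bundle.tables = {
        name: [{k.upper(): v for k, v in row.items()} for row in rows]
        for name, rows in bundle.tables.items()
    }
    truth = SyntheticTruth(
        config=cfg,
        true_rr=true_rr,
        expected_tables=expected,
        realized_tables=realized,
        duplicate_caseids=duplicate_caseids,
        n_target_cases=n_target,
        n_background_cases=n_background,
        cases=truth_cases,
        tto_days=tto_truth,
    )
    return bundle, truth


_FILE_COLUMNS = {
    "DEMO": ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
             "SEX", "WT", "WT_COD", "OCCP_COD", "OCCR_COUNTRY", "REPORTER_COUNTRY"],
    "DRUG": ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"],
    "REAC": ["PRIMARYID", "CASEID", "PT"],
    "THER": ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT", "END_DT"],
    "OUTC": ["PRIMARYID", "CASEID", "OUTC_COD"],
}


def write_bundle(
    bundle: RawBundle, truth: SyntheticTruth, out_dir: str | Path,
    delimiter: str = "$",
) -> list[Path]:
    """Write the five FAERS-dialect table files plus the truth table.

    Files carry one header row and '$'-delimited fields, and round-trip
    byte-consistently through :func:`faers_signals.faers_io.read_bundle`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, cols in _FILE_COLUMNS.items():
        path = out / f"{name}_synth.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(delimiter.join(cols) + "\n")
            for row in bundle.rows(name):
                fh.write(delimiter.join(row.get(c, "") for c in cols) + "\n")
        paths.append(path)
    truth_path = out / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("pt\ttrue_rr\texpected_a\texpected_b\texpected_c\texpected_d"
                 "\trealized_a\trealized_b\trealized_c\trealized_d\n")
        for pt in sorted(truth.true_rr):
            ea, eb, ec, ed = truth.expected_tables[pt]
            ra, rb, rc, rd_ = truth.realized_tables[pt]
            fh.write(f"{pt}\t{truth.true_rr[pt]}\t{ea:.4f}\t{eb:.4f}\t{ec:.4f}"
                     f"\t{ed:.4f}\t{ra}\t{rb}\t{rc}\t{rd_}\n")
    paths.append(truth_path)
    return paths
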