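"""Descriptive tables and the time-to-onset (TTO) analysis.

Covers the study's reporting tables — annual report volumes,
geographic and demographic distributions, reporting sources, serious
outcomes, primary indications — and the time-to-onset analysis with
time-stratified signal detection (early ≤30 days vs late >360 days).

Percentages are rounded half-up (1 decimal; 2 decimals for TTO) so
printed tables can be reproduced digit-for-digit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from . import disproportionality as dp
from .faers_io import is_full_date

TTO_BINS = ("0–30", "31–60", "61–90", "91–120", "121–150", "151–180", "181–360", ">360")
_TTO_EDGES = (30, 60, 90, 120, 150, 180, 360)

DIMENSIONS = ("country", "sex", "age_group", "reporting_source", "outcome")

#: reporter-occupation code → printed label (editable at call time)
OCCUPATION_LABELS = {
    "MD": "Physician",
    "CN": "Consumer",
    "OT": "Health professional",
    "RN": "Health professional",
    "PH": "Pharmacist",
    "LW": "Lawyer",
}

#: outcome code → printed label; OT and RI merge into one row
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Other serious / required intervention",
    "OT": "Other serious / required intervention",
}

MISSING_LABEL = "Missing/not reported"


def round_half_up(x: float, decimals: int) -> float:
    """Round-half-up, matching how printed tables round .5 upward."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, decimals)


@dataclass
class FrequencyTable:
    """Rows of (category, count, percent) over a stated denominator.

    ``multi_membership`` marks dimensions (outcomes) where one report
    may contribute to several rows, so counts need not sum to the
    denominator.
    """

    dimension: str
    rows: pd.DataFrame  # columns: category, count, percent
    denominator: int
    multi_membership: bool = False
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def _freq(counts: dict[str, int], dimension: str, denominator: int,
          decimals: int = 1, order: list[str] | None = None,
          multi: bool = False) -> FrequencyTable:
    cats = order if order is not None else sorted(
        counts, key=lambda c: (-counts[c], c)
    )
    rows = pd.DataFrame(
        {
            "category": cats,
            "count": [counts.get(c, 0) for c in cats],
            "percent": [percent(counts.get(c, 0), denominator, decimals) for c in cats],
        }
    )
    return FrequencyTable(dimension, rows, denominator, multi_membership=multi)


def annual_counts(cases: pd.DataFrame, cohort_ids: frozenset | set) -> FrequencyTable:
    """Reports per FDA-receipt year within a cohort, with percent of total.

    Year attribution follows the receipt date (``fda_dt``), matching
    the quarterly-file framing of the source data.
    """
    sub = cases[cases["primaryid"].isin(set(cohort_ids))]
    years = sub["fda_dt"].astype(str).str[:4]
    counts = years.value_counts().to_dict()
    denom = len(sub)
    return _freq(counts, "year", denom, order=sorted(counts))


def frequency_table(
    cases: pd.DataFrame,
    cohort_ids: frozenset | set,
    dimension: str,
    country_floor_pct: float = 1.0,
    occupation_labels: dict[str, str] = OCCUPATION_LABELS,
) -> FrequencyTable:
    """One descriptive distribution for a cohort.

    Missing values form an explicit category; country rows below
    ``country_floor_pct`` percent collapse into "All other countries";
    outcome rows use set semantics (denominator = cohort size).
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    sub = cases[cases["primaryid"].isin(set(cohort_ids))]
    denom = len(sub)

    if dimension == "country":
        vals = sub["reporter_country"].fillna(MISSING_LABEL).replace("", MISSING_LABEL)
        counts = vals.value_counts().to_dict()
        floor_n = denom * country_floor_pct / 100.0
        major = {c: n for c, n in counts.items()
                 if n >= floor_n and c != MISSING_LABEL}
        other = sum(n for c, n in counts.items() if c not in major and c != MISSING_LABEL)
        out = dict(major)
        if other:
            out["All other countries"] = other
        if MISSING_LABEL in counts:
            out[MISSING_LABEL] = counts[MISSING_LABEL]
        order = sorted(major, key=lambda c: (-major[c], c))
        order += [c for c in ("All other countries", MISSING_LABEL) if c in out]
        return _freq(out, dimension, denom, order=order)

    if dimension == "sex":
        mapped = sub["sex"].map({"F": "Female", "M": "Male"}).fillna(MISSING_LABEL)
        counts = mapped.value_counts().to_dict()
        order = [c for c in ("Female", "Male", MISSING_LABEL) if c in counts]
        return _freq(counts, dimension, denom, order=order)

    if dimension == "age_group":
        grp = sub["age_group"].replace("Missing", MISSING_LABEL)
        counts = grp.value_counts().to_dict()
        order = [g for g in ("<2", "2–11", "12–17", "18–64", "65–85", ">85",
                             MISSING_LABEL) if g in counts]
        return _freq(counts, dimension, denom, order=order)

    if dimension == "reporting_source":
        lab = sub["occp_cod"].map(occupation_labels)
        lab = lab.fillna("Missing / not specified")
        counts = lab.value_counts().to_dict()
        return _freq(counts, dimension, denom)

    # outcome: set semantics, one report may hit several rows
    counts: dict[str, int] = {}
    for outcomes in sub["outcomes"]:
        labels = {OUTCOME_LABELS[c] for c in outcomes if c in OUTCOME_LABELS}
        for lb in labels:
            counts[lb] = counts.get(lb, 0) + 1
    return _freq(counts, dimension, denom, multi=True)


def indication_table(
    indi: pd.DataFrame,
    drug: pd.DataFrame,
    cohort_ids: frozenset | set,
    grouping: dict[str, str] | None = None,
) -> FrequencyTable:
    """Primary-indication distribution for the cohort's PS drug rows.

    Indications are linked to the Primary Suspect drug via
    ``indi_drug_seq = drug_seq``; a term-group mapping (e.g. the
    postmenopausal and senile subtypes into "osteoporosis-related")
    aggregates verbatim terms.
    """
    grouping = grouping or {}
    ps = drug[(drug["role_cod"].fillna("") == "PS")
              & drug["primaryid"].isin(set(cohort_ids))]
    key = ps[["primaryid", "drug_seq"]].drop_duplicates()
    linked = indi.merge(
        key, left_on=["primaryid", "indi_drug_seq"],
        right_on=["primaryid", "drug_seq"], how="inner",
    )
    linked = linked[linked["indi_pt"].notna()]
    # one indication count per (report, term)
    linked = linked[["primaryid", "indi_pt"]].drop_duplicates()
    terms = linked["indi_pt"].map(lambda t: grouping.get(str(t).upper(), t))
    counts = terms.value_counts().to_dict()
    denom = int(linked["primaryid"].nunique())
    return _freq(counts, "indication", denom, multi=True)


def assign_tto_bin(tto_days: int) -> str:
    """Bin onset days with inclusive upper edges: [0,30], [31,60], …, (360,∞)."""
    for edge, label in zip(_TTO_EDGES, TTO_BINS):
        if tto_days <= edge:
            return label
    return TTO_BINS[-1]


def compute_tto(
    cases: pd.DataFrame,
    ther: pd.DataFrame,
    drug: pd.DataFrame,
    cohort_ids: frozenset | set,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Days from earliest PS-drug therapy start to the event date.

    Both dates must be complete 8-digit dates; negative intervals are
    excluded as implausible.  Returns (frame with primaryid, tto_days,
    bin) and a completeness log of exclusion counts.
    """
    log = {"partial_or_missing_dates": 0, "negative_tto": 0}
    sub = cases[cases["primaryid"].isin(set(cohort_ids))][["primaryid", "event_dt"]]
    ps = drug[(drug["role_cod"].fillna("") == "PS")
              & drug["primaryid"].isin(set(cohort_ids))][["primaryid", "drug_seq"]]
    th = ther.merge(
        ps.drop_duplicates(), left_on=["primaryid", "dsg_drug_seq"],
        right_on=["primaryid", "drug_seq"], how="inner",
    )
    th = th[th["start_dt"].map(is_full_date)]
    starts = th.groupby("primaryid")["start_dt"].min()

    merged = sub.assign(start_dt=sub["primaryid"].map(starts))
    ok = merged["event_dt"].map(is_full_date) & merged["start_dt"].notna()
    log["partial_or_missing_dates"] = int((~ok).sum())
    merged = merged[ok]
    if merged.empty:
        return pd.DataFrame(columns=["primaryid", "tto_days", "bin"]), log

    ev = pd.to_datetime(merged["event_dt"], format="%Y%m%d", errors="coerce")
    st = pd.to_datetime(merged["start_dt"], format="%Y%m%d", errors="coerce")
    days = (ev - st).dt.days
    valid = days.notna() & (days >= 0)
    log["partial_or_missing_dates"] += int(days.isna().sum())
    log["negative_tto"] = int((days < 0).sum())
    out = merged[valid][["primaryid"]].copy()
    out["tto_days"] = days[valid].astype(int)
    out["bin"] = out["tto_days"].map(assign_tto_bin)
    return out.reset_index(drop=True), log


def tto_table(tto_records: pd.DataFrame) -> FrequencyTable:
    """Onset-interval distribution over reports with TTO data (2-decimal %)."""
    if tto_records.empty:
        return FrequencyTable("tto", pd.DataFrame(columns=["category", "count", "percent"]), 0)
    counts = tto_records["bin"].value_counts().to_dict()
    denom = len(tto_records)
    order = [b for b in TTO_BINS if b in counts]
    return _freq(counts, "tto", denom, decimals=2, order=order)


def stratified_signals(
    cohort_ids: frozenset | set,
    reac: pd.DataFrame,
    retained_ids: set,
    strata: dict[str, set],
    thresholds: dict = dp.DEFAULT_THRESHOLDS,
    min_reports: int = 50,
    min_cases_reported: int = 1,
    gps_seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Re-run the full disproportionality stack inside report strata.

    ``strata`` maps stratum label → set of primaryids assignable to the
    stratum (e.g. TTO ≤30 vs >360 computed for *all* retained reports,
    or an age-group/sex partition).  The background for each stratum is
    restricted to that stratum's reports.  Strata with fewer than
    ``min_reports`` reports warn and are skipped.
    """
    out: dict[str, pd.DataFrame] = {}
    for label, ids in strata.items():
        stratum_ids = set(ids) & set(retained_ids)
        if len(stratum_ids) < min_reports:
            warnings.warn(
                f"stratum {label!r} has {len(stratum_ids)} reports "
                f"(< {min_reports}); skipped",
                stacklevel=2,
            )
            continue
        cohort_in = set(cohort_ids) & stratum_ids
        out[label] = dp.signal_table(
            cohort_in, reac, stratum_ids,
            thresholds=thresholds,
            min_cases_reported=min_cases_reported, gps_seed=gps_seed,
        )
    return out


def tto_strata(
    tto_by_report: pd.DataFrame, early_max: int = 30, late_min: int = 360
) -> dict[str, set]:
    """Early/late onset strata (≤30 d vs >360 d) from per-report TTO days."""
    early = set(tto_by_report.loc[tto_by_report["tto_days"] <= early_max, "primaryid"])
    late = set(tto_by_report.loc[tto_by_report["tto_days"] > late_min, "primaryid"])
    return {f"<={early_max}d": early, f">{late_min}d": late}
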