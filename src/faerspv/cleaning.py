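"""Case deduplication, demographic normalization, and primary-suspect cohorts.

The unit of analysis everywhere downstream is the deduplicated report:
for each FAERS case (``caseid``) only the version with the latest FDA
receipt date (``fda_dt``) is retained, ties broken by the largest
``primaryid``.  Cohorts collect retained reports in which the target
drug appears with role code ``PS`` (Primary Suspect), matching a
curated synonym dictionary against both the verbatim drug name and the
active-ingredient field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .faers_io import is_full_date

AGE_GROUPS = ("<2", "2–11", "12–17", "18–64", "65–85", ">85", "Missing")

#: multiplicative factor from age unit code to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_DOSAGE_RE = re.compile(r"\s+\d+(?:\.\d+)?\s*(?:MG|MCG|ML|G|IU|%)(?:/\S+)?$")


@dataclass
class CleaningLog:
    """Line-oriented accounting of records dropped during cleaning."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        if n:
            self.counts[reason] = self.counts.get(reason, 0) + int(n)

    def total_dropped(self) -> int:
        return sum(self.counts.values())

    def lines(self) -> list[str]:
        return [f"{reason}\t{n}" for reason, n in sorted(self.counts.items())]


@dataclass(frozen=True)
class DrugDictionary:
    """Canonical drug labels mapped to their uppercase synonym sets."""

    synonyms: dict[str, frozenset[str]]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for target, syns in self.synonyms.items():
            if not syns:
                raise ValueError(f"target {target!r} has an empty synonym set")
            for s in syns:
                if s in seen and seen[s] != target:
                    raise ValueError(
                        f"synonym {s!r} shared between {seen[s]!r} and {target!r}"
                    )
                seen[s] = target

    @classmethod
    def from_tsv(cls, stream) -> "DrugDictionary":
        """Load ``target<TAB>synonym`` rows, one synonym per row."""
        if isinstance(stream, str) and "\n" not in stream:
            with open(stream, encoding="utf-8") as fh:
                text = fh.read()
        elif isinstance(stream, str):
            text = stream
        else:
            text = stream.read()
        syns: dict[str, set[str]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            target, _, syn = line.partition("\t")
            if not syn:
                raise ValueError(f"malformed dictionary row {line!r}")
            syns.setdefault(target.strip(), set()).add(syn.strip().upper())
        return cls({t: frozenset(s) for t, s in syns.items()})

    def targets(self) -> list[str]:
        return sorted(self.synonyms)


@dataclass(frozen=True)
class Cohort:
    """Retained reports where the target is the Primary Suspect drug."""

    target_name: str
    primaryids: frozenset[str]

    def __len__(self) -> int:
        return len(self.primaryids)


def deduplicate_cases(
    demo: pd.DataFrame, log: CleaningLog | None = None
) -> set[str]:
    """Retain one report version per case: latest ``fda_dt``, then largest
    ``primaryid`` (numeric comparison when every id is numeric).

    Records missing ``caseid`` or without a full 8-digit ``fda_dt`` are
    dropped before grouping and counted in the cleaning log.
    """
    log = log if log is not None else CleaningLog()
    df = demo[["primaryid", "caseid", "fda_dt"]].copy()

    no_case = df["caseid"].isna() | (df["caseid"].astype("string").str.strip() == "")
    log.add("missing_caseid", int(no_case.sum()))
    df = df[~no_case]

    bad_dt = ~df["fda_dt"].map(is_full_date)
    log.add("unparseable_fda_dt", int(bad_dt.sum()))
    df = df[~bad_dt]
    if df.empty:
        return set()

    df = df.assign(_dt=df["fda_dt"].astype("int64"))
    pid_num = pd.to_numeric(df["primaryid"], errors="coerce")
    if pid_num.notna().all():
        df = df.assign(_pid=pid_num.astype("int64"))
    else:
        df = df.assign(_pid=df["primaryid"].astype(str))
    df = df.sort_values(["caseid", "_dt", "_pid"], kind="mergesort")
    kept = df.groupby("caseid", sort=False).tail(1)
    dup_versions = len(df) - len(kept)
    log.add("superseded_case_versions", dup_versions)
    return set(kept["primaryid"])


def filter_to_retained(records: pd.DataFrame, retained_ids: set[str]) -> pd.DataFrame:
    """Keep rows whose ``primaryid`` is in the retained set, order preserved."""
    if records.empty:
        return records
    mask = records["primaryid"].isin(retained_ids)
    return records[mask].reset_index(drop=True)


def normalize_age(age_value, age_cod, log: CleaningLog | None = None) -> float | None:
    """Convert a (value, unit-code) pair to years; unknown or negative → missing."""
    if age_value is None or age_value is pd.NA:
        return None
    try:
        v = float(age_value)
    except (TypeError, ValueError):
        return None
    if v < 0:
        if log is not None:
            log.add("negative_age")
        return None
    code = str(age_cod).strip().upper() if age_cod is not None and age_cod is not pd.NA else ""
    factor = AGE_UNIT_TO_YEARS.get(code)
    if factor is None:
        return None
    return v * factor


def assign_age_group(age_years: float | None) -> str:
    """Bin an age in years into the study's groups.

    Bins are [0,2), [2,12), [12,18), [18,65), [65,85], (85,∞): the
    "65–85" label is upper-inclusive, so 85.0 falls in the middle bin
    and only ages strictly above 85 are ">85".
    """
    if age_years is None or pd.isna(age_years):
        return "Missing"
    a = float(age_years)
    if a < 2:
        return "<2"
    if a < 12:
        return "2–11"
    if a < 18:
        return "12–17"
    if a < 65:
        return "18–64"
    if a <= 85:
        return "65–85"
    return ">85"


def normalize_drug_name(name) -> str:
    """Uppercase, trim, strip trailing punctuation and dosage tokens."""
    if name is None or name is pd.NA:
        return ""
    s = str(name).upper().strip()
    s = re.sub(r"\s+", " ", s)
    s = s.rstrip(" .,;:")
    s = _DOSAGE_RE.sub("", s)
    return s.rstrip(" .,;:")


def build_cohort(
    drug: pd.DataFrame,
    retained_ids: set[str],
    dictionary: DrugDictionary,
    target_name: str,
) -> Cohort:
    """Retained reports with ≥1 Primary Suspect row matching the target.

    Matching is exact on the normalized ``drugname`` or ``prod_ai``
    against the synonym set (not substring), mirroring a manually
    curated name dictionary.
    """
    if target_name not in dictionary.synonyms:
        raise KeyError(f"target {target_name!r} not in drug dictionary")
    syns = dictionary.synonyms[target_name]
    ps = drug[drug["role_cod"].fillna("") == "PS"]
    ps = ps[ps["primaryid"].isin(retained_ids)]
    name_match = ps["drugname"].map(normalize_drug_name).isin(syns)
    if "prod_ai" in ps.columns:
        ai_match = ps["prod_ai"].map(normalize_drug_name).isin(syns)
    else:
        ai_match = pd.Series(False, index=ps.index)
    hits = ps[name_match | ai_match]
    return Cohort(target_name=target_name, primaryids=frozenset(hits["primaryid"]))


def build_report_cases(
    demo: pd.DataFrame,
    retained_ids: set[str],
    outc: pd.DataFrame | None = None,
    rpsr: pd.DataFrame | None = None,
    log: CleaningLog | None = None,
) -> pd.DataFrame:
    """Assemble one cleaned row per retained report.

    Columns: primaryid, caseid, fda_dt, event_dt, age_years, age_group,
    sex, reporter_country, occp_cod, outcomes (frozenset of outcome
    codes), source_codes (frozenset of report-source codes).
    """
    cases = filter_to_retained(demo, retained_ids).copy()
    ages = [
        normalize_age(v, c, log)
        for v, c in zip(cases.get("age", pd.Series(dtype="string")),
                        cases.get("age_cod", pd.Series(dtype="string")))
    ] if len(cases) else []
    cases["age_years"] = pd.Series(ages, index=cases.index, dtype="float64") if len(cases) else pd.Series(dtype="float64")
    cases["age_group"] = cases["age_years"].map(assign_age_group) if len(cases) else pd.Series(dtype="object")
    sex = cases.get("sex", pd.Series(pd.NA, index=cases.index, dtype="string"))
    cases["sex"] = sex.where(sex.isin(["F", "M"]), "Missing").fillna("Missing")

    def _collect(table: pd.DataFrame | None, col: str) -> dict[str, frozenset]:
        if table is None or table.empty:
            return {}
        t = filter_to_retained(table, retained_ids)
        t = t[t[col].notna()]
        return {
            pid: frozenset(grp)
            for pid, grp in t.groupby("primaryid")[col]
        }

    out_map = _collect(outc, "outc_cod")
    src_map = _collect(rpsr, "rpsr_cod")
    cases["outcomes"] = cases["primaryid"].map(lambda p: out_map.get(p, frozenset()))
    cases["source_codes"] = cases["primaryid"].map(lambda p: src_map.get(p, frozenset()))
    return cases.reset_index(drop=True)
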