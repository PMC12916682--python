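"""Synthetic FAERS-format data with known ground truth.

Emits quarterly DEMO/DRUG/REAC/OUTC/RPSR/THER/INDI files in the
``$``-delimited dialect together with a :class:`TruthTable`, so every
pipeline stage — parsing, deduplication, cohorting, signal detection,
roll-up, time-to-onset — can be tested against planted truth without
downloading anything.

The generative model, per report (= one case):

* one Primary Suspect drug, drawn from a configured per-drug volume
  table (two target drugs plus a background pool that populates the
  comparator cells of every 2×2 table);
* events drawn per vocabulary PT as independent Bernoulli trials whose
  *odds* are multiplied by the planted relative rate for (drug, PT)
  pairs carrying a signal — odds-multiplication makes the generating
  ROR equal the configured rate, so recovery tests are interpretable;
* time-to-onset drawn from a per-drug log-normal (median, sigma),
  truncated at 0, emulating early-onset vs late-onset regimes;
* with probability ``duplicate_rate`` a case emits a second version
  sharing its caseid with an incremented primaryid and a strictly
  later FDA receipt date (the deduplication target);
* configurable missingness for age, sex, outcome and event date, and
  categorical distributions for country and reporter occupation.

All randomness flows from one ``numpy`` generator seeded from the
config, and rows are emitted in a fixed order, so the same (config,
seed) yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import faers_io

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class PlantedSignal(BaseModel):
    drug: str
    pt: str
    relative_rate: float = Field(ge=1.0)


class TTOModel(BaseModel):
    """Log-normal onset model: exp(N(ln median, sigma²)) days, floored at 0."""

    median_days: float = Field(gt=0)
    sigma: float = Field(gt=0)


class MissingRates(BaseModel):
    age: float = Field(default=0.5, ge=0, le=1)
    sex: float = Field(default=0.2, ge=0, le=1)
    outcome: float = Field(default=0.15, ge=0, le=1)
    event_dt: float = Field(default=0.15, ge=0, le=1)


class SimConfig(BaseModel):
    """Full specification of one synthetic FAERS dataset."""

    n_reports: dict[str, int]  # PS-drug name -> case count
    start_quarter: str = "2019Q2"
    end_quarter: str = "2025Q2"
    event_probs: dict[str, float]  # PT -> baseline report probability
    planted_signals: list[PlantedSignal] = Field(default_factory=list)
    duplicate_rate: float = Field(default=0.08, ge=0, le=1)
    missing_rates: MissingRates = Field(default_factory=MissingRates)
    country_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "US": 0.58, "JP": 0.15, "CA": 0.05, "GB": 0.05, "DE": 0.05,
            "FR": 0.04, "AU": 0.03, "ES": 0.03, "NL": 0.02,
        }
    )
    occupation_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "MD": 0.30, "CN": 0.30, "OT": 0.18, "PH": 0.10, "RN": 0.06, "": 0.06,
        }
    )
    outcome_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "HO": 0.12, "DE": 0.05, "DS": 0.015, "LT": 0.008,
            "CA": 0.001, "OT": 0.35, "RI": 0.02,
        }
    )
    tto_models: dict[str, TTOModel] = Field(default_factory=dict)
    default_tto: TTOModel = TTOModel(median_days=90.0, sigma=1.2)
    synonyms: dict[str, list[str]] = Field(default_factory=dict)  # drug -> names written
    indication_probs: dict[str, dict[str, float]] = Field(default_factory=dict)
    hierarchy: dict[str, tuple[str, str]] = Field(default_factory=dict)  # pt -> (hlt, soc)
    seed: int = 0

    @field_validator("event_probs")
    @classmethod
    def _probs_valid(cls, v):
        if not v:
            raise ValueError("event vocabulary must be nonempty")
        bad = {k: p for k, p in v.items() if not (0 < p < 1)}
        if bad:
            raise ValueError(f"event probabilities must lie in (0,1): {bad}")
        return v

    @model_validator(mode="after")
    def _cross_checks(self):
        vocab = set(self.event_probs)
        bad = [s.pt for s in self.planted_signals if s.pt not in vocab]
        if bad:
            raise ValueError(f"planted signal PTs not in vocabulary: {bad}")
        bad_drugs = [s.drug for s in self.planted_signals if s.drug not in self.n_reports]
        if bad_drugs:
            raise ValueError(f"planted signal drugs not in n_reports: {bad_drugs}")
        for q in (self.start_quarter, self.end_quarter):
            _parse_quarter(q)
        return self


def _parse_quarter(q: str) -> tuple[int, int]:
    try:
        year, qq = int(q[:4]), int(q[5])
        if q[4] != "Q" or not 1 <= qq <= 4:
            raise ValueError
    except (ValueError, IndexError):
        raise ValueError(f"quarter must look like 2019Q2, got {q!r}") from None
    return year, qq


def _quarter_list(start: str, end: str) -> list[tuple[int, int]]:
    (y0, q0), (y1, q1) = _parse_quarter(start), _parse_quarter(end)
    out = []
    y, q = y0, q0
    while (y, q) <= (y1, q1):
        out.append((y, q))
        q += 1
        if q == 5:
            y, q = y + 1, 1
    if not out:
        raise ValueError(f"empty quarter range {start}..{end}")
    return out


def _quarter_of(date: np.datetime64) -> tuple[int, int]:
    ts = pd.Timestamp(date)
    return ts.year, (ts.month - 1) // 3 + 1


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Ground truth emitted alongside the synthetic files."""

    relative_rates: dict[tuple[str, str], float]  # (drug, pt) -> RR
    lineage: dict[str, list[str]]  # caseid -> primaryids, receipt order
    retained: dict[str, str]  # caseid -> latest primaryid
    drug_of_case: dict[str, str]  # caseid -> PS drug
    n_cases: int = 0
    extras: dict = dfield(default_factory=dict)

    def cohort_size(self, drug: str) -> int:
        return sum(1 for d in self.drug_of_case.values() if d == drug)

    def to_json(self) -> str:
        return json.dumps(
            {
                "relative_rates": {f"{d}|{p}": r for (d, p), r in self.relative_rates.items()},
                "lineage": self.lineage,
                "retained": self.retained,
                "drug_of_case": self.drug_of_case,
                "n_cases": self.n_cases,
                "extras": self.extras,
            },
            indent=1, sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _odds_multiply(p: float, rr: float) -> float:
    """Event probability after multiplying the odds by ``rr``."""
    return p * rr / (1.0 - p + p * rr)


def expected_counts(config: SimConfig) -> pd.DataFrame:
    """Analytic per-(drug, PT) expectations under the sampling scheme.

    ``expected_a_bernoulli`` is the plain per-PT Bernoulli expectation
    n·p_eff; ``expected_a`` additionally accounts for the ≥1-event
    fallback draw (a report with no Bernoulli hit draws one PT from
    its effective weights), which inflates every pair by the factor
    1 + P(no hit)/Σp_eff.  Both ignore duplicate versions, i.e. they
    are expectations over unique cases — the unit of counting after
    deduplication.
    """
    rr_map = {(s.drug, s.pt): s.relative_rate for s in config.planted_signals}
    rows = []
    for drug, n in config.n_reports.items():
        p_eff = {
            pt: _odds_multiply(p, rr_map.get((drug, pt), 1.0))
            for pt, p in config.event_probs.items()
        }
        p_none = float(np.prod([1.0 - q for q in p_eff.values()]))
        s_eff = sum(p_eff.values())
        inflate = 1.0 + p_none / s_eff
        for pt, p in config.event_probs.items():
            rr = rr_map.get((drug, pt), 1.0)
            rows.append(
                {
                    "drug": drug, "pt": pt, "rr": rr, "baseline_p": p,
                    "p_effective": p_eff[pt],
                    "expected_a_bernoulli": n * p_eff[pt],
                    "expected_a": n * p_eff[pt] * inflate,
                }
            )
    df = pd.DataFrame(rows)
    ev_tot = df.groupby("pt")["expected_a"].transform("sum")
    n_total = sum(config.n_reports.values())
    df["expected_E"] = df["drug"].map(config.n_reports) * ev_tot / n_total
    return df


def _fmt_dates(days: np.ndarray, mask_missing: np.ndarray | None = None) -> list[str]:
    dates = pd.to_datetime(days.astype("datetime64[D]"))
    out = dates.strftime("%Y%m%d").to_numpy(dtype=object)
    if mask_missing is not None:
        out[mask_missing] = ""
    return list(out)


def generate_dataset(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[dict[str, str], TruthTable]:
    """Generate quarterly FAERS files and their truth table.

    Returns ``(files, truth)`` where ``files`` maps filenames like
    ``DEMO20Q3.txt`` to file text.  When ``out_dir`` is given the
    files, the truth table (``truth.json``) and supporting config
    files (drug dictionary, hierarchy, watchlists) are also written.
    """
    rng = np.random.default_rng(config.seed)
    quarters = _quarter_list(config.start_quarter, config.end_quarter)
    q_starts = np.array(
        [np.datetime64(f"{y}-{3 * (q - 1) + 1:02d}-01") for y, q in quarters]
    )
    q_ends = np.array(
        [
            np.datetime64(f"{y + 1}-01-01") if q == 4
            else np.datetime64(f"{y}-{3 * q + 1:02d}-01")
            for y, q in quarters
        ]
    )
    q_len = (q_ends - q_starts).astype(int)

    pts = sorted(config.event_probs)
    base_p = np.array([config.event_probs[pt] for pt in pts])
    rr_map = {(s.drug, s.pt): s.relative_rate for s in config.planted_signals}
    mr = config.missing_rates
    countries = sorted(config.country_probs)
    c_p = np.array([config.country_probs[c] for c in countries], dtype=float)
    c_p = c_p / c_p.sum()
    occs = sorted(config.occupation_probs)
    o_p = np.array([config.occupation_probs[o] for o in occs], dtype=float)
    o_p = o_p / o_p.sum()
    out_codes = sorted(config.outcome_probs)
    drugs = sorted(config.n_reports)
    bg_pool = [d for d in drugs if d not in config.synonyms]

    demo_rows, drug_rows, reac_rows, outc_rows = [], [], [], []
    rpsr_rows, ther_rows, indi_rows = [], [], []
    truth = TruthTable({}, {}, {}, {}, 0)
    for drug, n in config.n_reports.items():
        for pt in pts:
            truth.relative_rates[(drug, pt)] = rr_map.get((drug, pt), 1.0)

    case_counter = 1_000_000
    for drug in drugs:
        n = config.n_reports[drug]
        eff_p = np.array(
            [_odds_multiply(p, rr_map.get((drug, pt), 1.0)) for pt, p in zip(pts, base_p)]
        )
        ev = rng.random((n, len(pts))) < eff_p
        none = ~ev.any(axis=1)
        if none.any():
            # fallback draw for empty reports uses the report's effective
            # (planted-adjusted) weights so the generating ROR stays at the
            # configured relative rate
            fallback = rng.choice(len(pts), size=int(none.sum()), p=eff_p / eff_p.sum())
            ev[np.flatnonzero(none), fallback] = True

        qi = rng.integers(0, len(quarters), size=n)
        day_off = (rng.random(n) * q_len[qi]).astype(int)
        fda = q_starts[qi] + day_off.astype("timedelta64[D]")
        lag = rng.integers(0, 61, size=n).astype("timedelta64[D]")
        event = fda - lag
        tm = config.tto_models.get(drug, config.default_tto)
        tto = np.floor(
            np.exp(rng.normal(np.log(tm.median_days), tm.sigma, size=n))
        ).astype(int)
        tto = np.maximum(tto, 0)
        start = event - tto.astype("timedelta64[D]")

        age = np.clip(rng.normal(70, 12, size=n), 18, 100).round(0)
        age_missing = rng.random(n) < mr.age
        sex = np.where(rng.random(n) < 0.70, "F", "M").astype(object)
        sex[rng.random(n) < mr.sex] = ""
        country = np.array(countries, dtype=object)[
            rng.choice(len(countries), size=n, p=c_p)
        ]
        occ = np.array(occs, dtype=object)[rng.choice(len(occs), size=n, p=o_p)]
        out_mask = rng.random((n, len(out_codes))) < np.array(
            [config.outcome_probs[c] for c in out_codes]
        )
        out_mask[rng.random(n) < mr.outcome] = False
        ev_missing = rng.random(n) < mr.event_dt
        dup = rng.random(n) < config.duplicate_rate
        dup_delta = rng.integers(1, 181, size=n).astype("timedelta64[D]")
        n_con = rng.integers(0, 3, size=n)

        names = config.synonyms.get(drug, [drug])
        name_idx = rng.integers(0, len(names), size=n)
        ind_probs = config.indication_probs.get(drug)
        if ind_probs:
            ind_terms = sorted(ind_probs)
            ip = np.array([ind_probs[t] for t in ind_terms], dtype=float)
            has_indi = rng.random(n) < min(ip.sum(), 1.0)
            ind_choice = rng.choice(len(ind_terms), size=n, p=ip / ip.sum())
        else:
            has_indi = np.zeros(n, dtype=bool)
            ind_choice = np.zeros(n, dtype=int)

        fda_s = _fmt_dates(fda)
        ev_s = _fmt_dates(event, ev_missing)
        st_s = _fmt_dates(start)
        dup_s = _fmt_dates(fda + dup_delta)

        for i in range(n):
            case_counter += 1
            caseid = str(case_counter)
            versions = [(f"{caseid}1", fda_s[i])]
            if dup[i]:
                versions.append((f"{caseid}2", dup_s[i]))
            truth.lineage[caseid] = [v[0] for v in versions]
            truth.retained[caseid] = versions[-1][0]
            truth.drug_of_case[caseid] = drug
            truth.n_cases += 1

            con = [bg_pool[j % len(bg_pool)]
                   for j in rng.integers(0, len(bg_pool), size=int(n_con[i]))] if bg_pool else []
            my_pts = [pts[j] for j in np.flatnonzero(ev[i])]
            src = "HP" if occ[i] in ("MD", "PH", "RN", "OT") else "CSM"

            for pid, fdt in versions:
                demo_rows.append(
                    (pid, caseid, fdt, ev_s[i],
                     "" if age_missing[i] else f"{age[i]:.0f}",
                     "" if age_missing[i] else "YR",
                     sex[i], country[i], occ[i])
                )
                drug_rows.append((pid, "1", "PS", names[name_idx[i]], drug))
                for k, cdrug in enumerate(con, start=2):
                    drug_rows.append((pid, str(k), "C", cdrug, cdrug))
                for pt in my_pts:
                    reac_rows.append((pid, pt))
                for j, code in enumerate(out_codes):
                    if out_mask[i, j]:
                        outc_rows.append((pid, code))
                rpsr_rows.append((pid, src))
                ther_rows.append((pid, "1", st_s[i], ""))
                if has_indi[i]:
                    indi_rows.append((pid, "1", ind_terms[ind_choice[i]]))

    frames = {
        "demo": pd.DataFrame(
            demo_rows,
            columns=["primaryid", "caseid", "fda_dt", "event_dt", "age",
                     "age_cod", "sex", "reporter_country", "occp_cod"],
        ),
        "drug": pd.DataFrame(
            drug_rows, columns=["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]
        ),
        "reac": pd.DataFrame(reac_rows, columns=["primaryid", "pt"]),
        "outc": pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"]),
        "rpsr": pd.DataFrame(rpsr_rows, columns=["primaryid", "rpsr_cod"]),
        "ther": pd.DataFrame(
            ther_rows, columns=["primaryid", "dsg_drug_seq", "start_dt", "end_dt"]
        ),
        "indi": pd.DataFrame(indi_rows, columns=["primaryid", "indi_drug_seq", "indi_pt"]),
    }

    # split per quarter on the DEMO receipt date; child tables follow DEMO
    demo = frames["demo"]
    qlabel = demo["fda_dt"].map(
        lambda s: "{}Q{}".format(s[2:4], (int(s[4:6]) - 1) // 3 + 1)
    )
    pid_quarter = dict(zip(demo["primaryid"], qlabel))
    files: dict[str, str] = {}
    for kind, df in frames.items():
        if df.empty:
            continue
        qs = df["primaryid"].map(pid_quarter)
        for ql in sorted(qs.unique()):
            sub = df[qs == ql]
            files[f"{kind.upper()}{ql}.txt"] = faers_io.write_faers_table(sub, kind)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, text in files.items():
            (out_dir / name).write_text(text, encoding="utf-8")
        (out_dir / "truth.json").write_text(truth.to_json(), encoding="utf-8")
        (out_dir / "drug_dictionary.tsv").write_text(
            dictionary_tsv(config), encoding="utf-8"
        )
        (out_dir / "hierarchy.tsv").write_text(hierarchy_tsv(config), encoding="utf-8")
    return files, truth


def dictionary_tsv(config: SimConfig) -> str:
    """Drug-dictionary TSV covering the configured target synonym sets."""
    lines = []
    for drug in sorted(config.synonyms):
        for syn in sorted(set(config.synonyms[drug]) | {drug}):
            lines.append(f"{drug}\t{syn}")
    return "\n".join(lines) + "\n"


def hierarchy_tsv(config: SimConfig) -> str:
    """PT→HLT→SOC TSV for the configured synthetic hierarchy."""
    lines = [
        f"{pt}\t{hlt}\t{soc}"
        for pt, (hlt, soc) in sorted(config.hierarchy.items())
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Default study-like configuration
# ---------------------------------------------------------------------------

#: synthetic MedDRA-style hierarchy: PT -> (HLT, SOC)
DEFAULT_HIERARCHY: dict[str, tuple[str, str]] = {
    "FEMUR FRACTURE": ("Fractures", "Musculoskeletal and connective tissue disorders"),
    "SPINAL COMPRESSION FRACTURE": ("Fractures", "Musculoskeletal and connective tissue disorders"),
    "HUMERUS FRACTURE": ("Fractures", "Musculoskeletal and connective tissue disorders"),
    "OSTEONECROSIS OF JAW": ("Bone disorders", "Musculoskeletal and connective tissue disorders"),
    "BONE PAIN": ("Bone disorders", "Musculoskeletal and connective tissue disorders"),
    "ARTHRALGIA": ("Joint related signs and symptoms", "Musculoskeletal and connective tissue disorders"),
    "BACK PAIN": ("Musculoskeletal and connective tissue pain", "Musculoskeletal and connective tissue disorders"),
    "MYALGIA": ("Muscle pains", "Musculoskeletal and connective tissue disorders"),
    "PAIN IN EXTREMITY": ("Musculoskeletal and connective tissue pain", "Musculoskeletal and connective tissue disorders"),
    "HYPOCALCAEMIA": ("Calcium metabolism disorders", "Metabolism and nutrition disorders"),
    "HYPERCALCAEMIA": ("Calcium metabolism disorders", "Metabolism and nutrition disorders"),
    "DECREASED APPETITE": ("Appetite disorders", "Metabolism and nutrition disorders"),
    "MYOCARDIAL INFARCTION": ("Ischaemic coronary artery disorders", "Cardiac disorders"),
    "ANGINA PECTORIS": ("Ischaemic coronary artery disorders", "Cardiac disorders"),
    "CARDIAC FAILURE": ("Heart failures", "Cardiac disorders"),
    "CARDIAC FAILURE CONGESTIVE": ("Heart failures", "Cardiac disorders"),
    "ATRIAL FIBRILLATION": ("Supraventricular arrhythmias", "Cardiac disorders"),
    "CEREBROVASCULAR ACCIDENT": ("Central nervous system vascular disorders", "Nervous system disorders"),
    "ISCHAEMIC STROKE": ("Central nervous system vascular disorders", "Nervous system disorders"),
    "HEADACHE": ("Headaches", "Nervous system disorders"),
    "DIZZINESS": ("Neurological signs and symptoms", "Nervous system disorders"),
    "INJECTION SITE URTICARIA": ("Administration site reactions", "General disorders and administration site conditions"),
    "INJECTION SITE ERYTHEMA": ("Administration site reactions", "General disorders and administration site conditions"),
    "INJECTION SITE PAIN": ("Administration site reactions", "General disorders and administration site conditions"),
    "FATIGUE": ("Asthenic conditions", "General disorders and administration site conditions"),
    "PYREXIA": ("Febrile disorders", "General disorders and administration site conditions"),
    "DEATH": ("Death and sudden death", "General disorders and administration site conditions"),
    "DRUG INEFFECTIVE": ("Therapeutic and nontherapeutic responses", "General disorders and administration site conditions"),
    "NONINFECTIVE GINGIVITIS": ("Dental and gingival conditions", "Gastrointestinal disorders"),
    "TOOTHACHE": ("Dental and gingival conditions", "Gastrointestinal disorders"),
    "NAUSEA": ("Nausea and vomiting symptoms", "Gastrointestinal disorders"),
    "VOMITING": ("Nausea and vomiting symptoms", "Gastrointestinal disorders"),
    "DIARRHOEA": ("Diarrhoea symptoms", "Gastrointestinal disorders"),
    "STEROID THERAPY": ("Endocrine gland therapeutic procedures", "Surgical and medical procedures"),
    "RASH": ("Rashes, eruptions and exanthems", "Skin and subcutaneous tissue disorders"),
    "PRURITUS": ("Pruritus NEC", "Skin and subcutaneous tissue disorders"),
    "FALL": ("Non-site specific injuries", "Injury, poisoning and procedural complications"),
    "PRODUCT STORAGE ERROR": ("Product storage errors", "Injury, poisoning and procedural complications"),
}

#: baseline per-report probabilities for the default vocabulary
DEFAULT_EVENT_PROBS: dict[str, float] = {
    "FEMUR FRACTURE": 0.006, "SPINAL COMPRESSION FRACTURE": 0.005,
    "HUMERUS FRACTURE": 0.004, "OSTEONECROSIS OF JAW": 0.003,
    "BONE PAIN": 0.010, "ARTHRALGIA": 0.030, "BACK PAIN": 0.025,
    "MYALGIA": 0.020, "PAIN IN EXTREMITY": 0.020,
    "HYPOCALCAEMIA": 0.004, "HYPERCALCAEMIA": 0.003, "DECREASED APPETITE": 0.012,
    "MYOCARDIAL INFARCTION": 0.008, "ANGINA PECTORIS": 0.005,
    "CARDIAC FAILURE": 0.007, "CARDIAC FAILURE CONGESTIVE": 0.004,
    "ATRIAL FIBRILLATION": 0.008,
    "CEREBROVASCULAR ACCIDENT": 0.007, "ISCHAEMIC STROKE": 0.004,
    "HEADACHE": 0.040, "DIZZINESS": 0.035,
    "INJECTION SITE URTICARIA": 0.003, "INJECTION SITE ERYTHEMA": 0.004,
    "INJECTION SITE PAIN": 0.012,
    "FATIGUE": 0.045, "PYREXIA": 0.020, "DEATH": 0.030, "DRUG INEFFECTIVE": 0.050,
    "NONINFECTIVE GINGIVITIS": 0.002, "TOOTHACHE": 0.006,
    "NAUSEA": 0.045, "VOMITING": 0.025, "DIARRHOEA": 0.030,
    "STEROID THERAPY": 0.002,
    "RASH": 0.025, "PRURITUS": 0.018,
    "FALL": 0.025, "PRODUCT STORAGE ERROR": 0.008,
}

DENOSUMAB = "DENOSUMAB"
ROMOSOZUMAB = "ROMOSOZUMAB"

#: planted (drug, PT, relative rate): a late-onset skeletal/metabolic
#: profile for the denosumab-like target, an early-onset cardiovascular
#: and injection-site profile for the romosozumab-like target
DEFAULT_PLANTED: list[tuple[str, str, float]] = [
    (DENOSUMAB, "FEMUR FRACTURE", 8.0),
    (DENOSUMAB, "SPINAL COMPRESSION FRACTURE", 8.0),
    (DENOSUMAB, "OSTEONECROSIS OF JAW", 12.0),
    (DENOSUMAB, "HYPOCALCAEMIA", 10.0),
    (DENOSUMAB, "NONINFECTIVE GINGIVITIS", 6.0),
    (DENOSUMAB, "STEROID THERAPY", 5.0),
    (DENOSUMAB, "PRODUCT STORAGE ERROR", 5.0),
    (ROMOSOZUMAB, "MYOCARDIAL INFARCTION", 8.0),
    (ROMOSOZUMAB, "ANGINA PECTORIS", 6.0),
    (ROMOSOZUMAB, "CARDIAC FAILURE", 6.0),
    (ROMOSOZUMAB, "CEREBROVASCULAR ACCIDENT", 5.0),
    (ROMOSOZUMAB, "INJECTION SITE URTICARIA", 10.0),
    (ROMOSOZUMAB, "INJECTION SITE ERYTHEMA", 6.0),
]

#: direct immune watchlist (type-I hypersensitivity and local
#: immune-inflammatory PTs); indirect: treatment-consequence markers
DEFAULT_DIRECT_WATCHLIST = (
    "NONINFECTIVE GINGIVITIS",
    "INJECTION SITE URTICARIA",
    "INJECTION SITE ERYTHEMA",
)
DEFAULT_INDIRECT_WATCHLIST = ("STEROID THERAPY",)


def default_config(seed: int = 0, scale: float = 1.0) -> SimConfig:
    """The default study-like conditions: 2 targets + 20 background drugs,
    ~50,000 cases, late-onset (median 400 d) vs early-onset (median 25 d)
    exposure-to-event regimes, with the planted-signal profiles above.

    ``scale`` shrinks every per-drug volume proportionally for quick
    fixtures; the study conditions are ``scale=1``.
    """
    n = {
        DENOSUMAB: max(int(8000 * scale), 10),
        ROMOSOZUMAB: max(int(2000 * scale), 10),
    }
    for i in range(1, 21):
        n[f"BGDRUG{i:02d}"] = max(int(2000 * scale), 10)
    return SimConfig(
        n_reports=n,
        event_probs=DEFAULT_EVENT_PROBS,
        planted_signals=[
            PlantedSignal(drug=d, pt=p, relative_rate=r) for d, p, r in DEFAULT_PLANTED
        ],
        tto_models={
            DENOSUMAB: TTOModel(median_days=400.0, sigma=0.8),
            ROMOSOZUMAB: TTOModel(median_days=25.0, sigma=0.8),
        },
        synonyms={
            DENOSUMAB: ["PROLIA", "XGEVA", "DENOSUMAB", "PROLIA 60MG"],
            ROMOSOZUMAB: ["EVENITY", "ROMOSOZUMAB"],
        },
        indication_probs={
            DENOSUMAB: {
                "OSTEOPOROSIS": 0.35, "OSTEOPOROSIS POSTMENOPAUSAL": 0.15,
                "SENILE OSTEOPOROSIS": 0.04,
                "BONE METASTASES": 0.10, "BREAST CANCER": 0.06,
            },
            ROMOSOZUMAB: {
                "OSTEOPOROSIS": 0.40, "OSTEOPOROSIS POSTMENOPAUSAL": 0.20,
                "SENILE OSTEOPOROSIS": 0.05,
            },
        },
        hierarchy=DEFAULT_HIERARCHY,
        seed=seed,
    )
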