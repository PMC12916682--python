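"""End-to-end orchestration: ingest → clean → cohort → signals → roll-up
→ stratify → classify → report.

``run_pipeline`` is a pure function of (input files, config): it emits
per-target PT/HLT/SOC signal CSVs, descriptive tables, time-to-onset
tables, time-stratified signal tables, an immune-classification CSV and
a run manifest, and reruns with the same inputs produce byte-identical
CSVs.  Every dropped record is attributed to exactly one logged reason
so the manifest reconstructs the report-selection flowchart.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import cleaning, descriptives, disproportionality as dp, hierarchy as hi
from .faers_io import TABLE_SCHEMAS, concat_quarters, parse_faers_table

__version__ = "0.1.0"

CSV_FLOAT_FORMAT = "%.6g"


class Thresholds(BaseModel):
    ror_ci_lo: float = Field(default=1.0, gt=0)
    min_cases: int = Field(default=3, gt=0)
    prr_min: float = Field(default=2.0, gt=0)
    chi2_min: float = Field(default=4.0, gt=0)
    ebgm05_min: float = Field(default=2.0, gt=0)
    ic025_min: float = Field(default=0.0, ge=0)

    def as_dict(self) -> dict:
        return self.model_dump()


class RunConfig(BaseModel, extra="forbid"):
    input_dir: str
    output_dir: str
    drug_dictionary: str
    targets: list[str] = Field(min_length=1)
    hierarchy: str
    direct_watchlist: str | None = None
    indirect_watchlist: str | None = None
    thresholds: Thresholds = Field(default_factory=Thresholds)
    stratify: list[str] = Field(default_factory=lambda: ["tto"])  # tto|age_group|sex
    hlt_policy: str = "refit"  # refit | reuse
    country_floor_pct: float = 1.0
    min_stratum_reports: int = 50
    min_cases_reported: int = 1
    seed: int = 0

    def check_paths(self) -> None:
        problems = []
        for name in ("input_dir", "drug_dictionary", "hierarchy",
                     "direct_watchlist", "indirect_watchlist"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name}: path {p!r} does not exist")
        if problems:
            raise FileNotFoundError("; ".join(problems))


def validate_config(raw: str | dict) -> RunConfig:
    """Schema-check a JSON/YAML config; errors list every violation."""
    if isinstance(raw, str):
        try:
            data = json.loads(raw)
        except json.JSONDecodeError:
            import yaml  # optional dialect; config is usually JSON

            data = yaml.safe_load(raw)
    else:
        data = raw
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        msgs = [f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()]
        raise ValueError("invalid run config: " + "; ".join(msgs)) from exc


def load_quarterly_tables(input_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read every ``<KIND>yyQq.txt`` file and concatenate per table kind."""
    input_dir = Path(input_dir)
    tables: dict[str, list[pd.DataFrame]] = {k: [] for k in TABLE_SCHEMAS}
    pat = re.compile(r"^([a-z]{4})\d{2}q\d\.txt$")
    for path in sorted(input_dir.glob("*.txt")):
        m = pat.match(path.name.lower())
        if m and m.group(1) in tables:
            tables[m.group(1)].append(parse_faers_table(str(path), m.group(1)))
    return {
        kind: concat_quarters(parts) if parts else pd.DataFrame()
        for kind, parts in tables.items()
    }


def _write_freq(ft: descriptives.FrequencyTable, path: Path, written: list[Path]) -> None:
    ft.rows.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    side = path.with_suffix(".json")
    side.write_text(
        json.dumps(
            {
                "dimension": ft.dimension,
                "denominator": ft.denominator,
                "multi_membership": ft.multi_membership,
            },
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    written.extend([path, side])


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis; returns the manifest dict (also written).

    Any stage failure aborts with the stage name in the message and
    removes partial outputs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "validate"
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    def tick(name: str) -> None:
        nonlocal t0
        timings[name] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()

    try:
        config.check_paths()
        stage = "ingest"
        tables = load_quarterly_tables(config.input_dir)
        demo = tables["demo"]
        if demo.empty:
            raise ValueError(f"no DEMO files found under {config.input_dir}")
        checksums = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(config.input_dir).glob("*.txt"))
        }
        tick("ingest")

        stage = "clean"
        log = cleaning.CleaningLog()
        retained = cleaning.deduplicate_cases(demo, log)
        filtered = {
            kind: cleaning.filter_to_retained(df, retained)
            for kind, df in tables.items()
            if not df.empty
        }
        cases = cleaning.build_report_cases(
            demo, retained, outc=tables.get("outc"), rpsr=tables.get("rpsr"), log=log
        )
        (out_dir / "cleaning_log.txt").write_text(
            "\n".join(log.lines()) + "\n", encoding="utf-8"
        )
        written.append(out_dir / "cleaning_log.txt")
        tick("clean")

        stage = "cohort"
        dictionary = cleaning.DrugDictionary.from_tsv(config.drug_dictionary)
        cohorts = {
            t: cleaning.build_cohort(filtered["drug"], retained, dictionary, t)
            for t in config.targets
        }
        tick("cohort")

        stage = "hierarchy-load"
        meddra = hi.MeddraMap.from_tsv(config.hierarchy)
        direct = (
            hi.load_watchlist(config.direct_watchlist)
            if config.direct_watchlist
            else frozenset()
        )
        indirect = (
            hi.load_watchlist(config.indirect_watchlist)
            if config.indirect_watchlist
            else frozenset()
        )
        tick("hierarchy-load")

        thresholds = config.thresholds.as_dict()
        reac = filtered["reac"]
        manifest_counts = {
            "raw_reports": int(len(demo)),
            "deduplicated_reports": int(len(retained)),
            "dropped": dict(log.counts),
            "cohort_sizes": {t: len(c) for t, c in cohorts.items()},
        }

        for target, cohort in cohorts.items():
            slug = target.lower()

            stage = f"signals[{target}]"
            pt_tables = dp.contingency_frame(cohort.primaryids, reac, retained)
            pt_hp = dp.fit_gps(pt_tables, seed=config.seed)
            pt_sig = dp.signal_table(
                cohort.primaryids, reac, retained, hyperparams=pt_hp,
                thresholds=thresholds,
                min_cases_reported=config.min_cases_reported,
            )
            p = out_dir / f"signals_{slug}_pt.csv"
            pt_sig.to_csv(p, index=False, float_format=CSV_FLOAT_FORMAT)
            written.append(p)
            tick(stage)

            stage = f"rollup[{target}]"
            hlt_sig_by_level = {}
            for level in hi.LEVELS:
                rolled, unmapped = hi.rollup_events(reac, meddra, level)
                sig = hi.signals_at_level(
                    cohort.primaryids, rolled, retained,
                    hyperparams_policy=config.hlt_policy, pt_hyperparams=pt_hp,
                    thresholds=thresholds,
                    min_cases_reported=config.min_cases_reported,
                    gps_seed=config.seed,
                )
                if level == "HLT":
                    members = hi.member_pts(sig, pt_sig, meddra)
                    sig = sig.assign(
                        member_pts=sig["event_term"].map(
                            lambda h: ";".join(members.get(h, []))
                        )
                    )
                p = out_dir / f"signals_{slug}_{level.lower()}.csv"
                sig.to_csv(p, index=False, float_format=CSV_FLOAT_FORMAT)
                written.append(p)
                hlt_sig_by_level[level] = sig
                if level == "HLT" and len(unmapped):
                    p = out_dir / f"unmapped_pts_{slug}.csv"
                    unmapped.to_csv(p, index=False)
                    written.append(p)
            tick(stage)

            stage = f"immune[{target}]"
            hlt_sig = hlt_sig_by_level["HLT"]
            confirmed_hlts = sorted(hlt_sig.loc[hlt_sig["confirmed"], "event_term"])
            members = hi.member_pts(hlt_sig, pt_sig, meddra)
            classes = hi.classify_immune(confirmed_hlts, members, direct, indirect)
            p = out_dir / f"immune_{slug}.csv"
            hi.classification_frame(classes).to_csv(p, index=False)
            written.append(p)
            tick(stage)

            stage = f"descriptives[{target}]"
            _write_freq(
                descriptives.annual_counts(cases, cohort.primaryids),
                out_dir / f"annual_{slug}.csv", written,
            )
            for dim in descriptives.DIMENSIONS:
                _write_freq(
                    descriptives.frequency_table(
                        cases, cohort.primaryids, dim,
                        country_floor_pct=config.country_floor_pct,
                    ),
                    out_dir / f"{dim}_{slug}.csv", written,
                )
            if "indi" in filtered:
                _write_freq(
                    descriptives.indication_table(
                        filtered["indi"], filtered["drug"], cohort.primaryids,
                        grouping=OSTEOPOROSIS_GROUPING,
                    ),
                    out_dir / f"indication_{slug}.csv", written,
                )
            tto, tto_log = descriptives.compute_tto(
                cases, filtered["ther"], filtered["drug"], cohort.primaryids
            )
            _write_freq(
                descriptives.tto_table(tto), out_dir / f"tto_{slug}.csv", written
            )
            (out_dir / f"tto_log_{slug}.json").write_text(
                json.dumps(tto_log, sort_keys=True) + "\n", encoding="utf-8"
            )
            written.append(out_dir / f"tto_log_{slug}.json")
            tick(stage)

            stage = f"stratify[{target}]"
            strata: dict[str, set] = {}
            if "tto" in config.stratify:
                all_tto, _ = descriptives.compute_tto(
                    cases, filtered["ther"], filtered["drug"], retained
                )
                strata.update(descriptives.tto_strata(all_tto))
            if "age_group" in config.stratify:
                for g, grp in cases.groupby("age_group"):
                    strata[f"age:{g}"] = set(grp["primaryid"])
            if "sex" in config.stratify:
                for s, grp in cases.groupby("sex"):
                    strata[f"sex:{s}"] = set(grp["primaryid"])
            unknown = [s for s in config.stratify if s not in ("tto", "age_group", "sex")]
            if unknown:
                raise ValueError(f"unknown stratification key(s): {unknown}")
            strat = descriptives.stratified_signals(
                cohort.primaryids, reac, retained, strata,
                thresholds=thresholds,
                min_reports=config.min_stratum_reports,
                min_cases_reported=config.min_cases_reported,
                gps_seed=config.seed,
            )
            for label, table in strat.items():
                safe = label.replace(":", "_").replace("<", "le").replace(">", "gt")
                safe = safe.replace("=", "").replace("–", "-")
                p = out_dir / f"stratified_{slug}_{safe}.csv"
                table.to_csv(p, index=False, float_format=CSV_FLOAT_FORMAT)
                written.append(p)
            tick(stage)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": config.model_dump(),
            "input_checksums": checksums,
            "counts": manifest_counts,
            "timings_s": timings,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest
    except Exception as exc:
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


#: default verbatim-indication grouping (osteoporosis and its subtypes)
OSTEOPOROSIS_GROUPING = {
    "OSTEOPOROSIS": "Osteoporosis-related",
    "OSTEOPOROSIS POSTMENOPAUSAL": "Osteoporosis-related",
    "SENILE OSTEOPOROSIS": "Osteoporosis-related",
    "POSTMENOPAUSAL OSTEOPOROSIS": "Osteoporosis-related",
    "OSTEOPENIA": "Osteoporosis-related",
}
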