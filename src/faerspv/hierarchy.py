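"""PT→HLT→SOC roll-up and immune-related classification of HLT signals.

MedDRA itself is licensed, so the hierarchy is a user-supplied,
pre-flattened primary-path mapping (one HLT per PT, one SOC per HLT).
Events are aggregated with unique-report counting: a report maps to an
HLT (or SOC) once if at least one of its PTs belongs there, and the
full disproportionality stack is re-run on the aggregated pairs.

An HLT signal is classified *immune-related* when at least one of its
significant member PTs appears on a direct immune watchlist (e.g.
injection-site urticaria), *immune-related-indirect* when only an
indirect marker such as steroid therapy is present, else
*non-immune-related*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import disproportionality as dp

LEVELS = ("HLT", "SOC")


@dataclass(frozen=True)
class MeddraMap:
    """Flattened primary-path PT→HLT→SOC mapping."""

    pt_to_hlt: dict[str, str]
    hlt_to_soc: dict[str, str]

    @classmethod
    def from_tsv(cls, stream) -> "MeddraMap":
        """Load ``pt<TAB>hlt<TAB>soc`` rows; conflicting duplicates error."""
        if isinstance(stream, str) and "\n" not in stream:
            with open(stream, encoding="utf-8") as fh:
                text = fh.read()
        elif isinstance(stream, str):
            text = stream
        else:
            text = stream.read()
        pt_to_hlt: dict[str, str] = {}
        hlt_to_soc: dict[str, str] = {}
        n_rows = 0
        for i, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {i}: expected pt<TAB>hlt<TAB>soc, got {line!r}")
            pt, hlt, soc = (p.strip() for p in parts)
            n_rows += 1
            if pt in pt_to_hlt and pt_to_hlt[pt] != hlt:
                raise ValueError(
                    f"line {i}: PT {pt!r} maps to both {pt_to_hlt[pt]!r} and {hlt!r}"
                )
            if hlt in hlt_to_soc and hlt_to_soc[hlt] != soc:
                raise ValueError(
                    f"line {i}: HLT {hlt!r} maps to both {hlt_to_soc[hlt]!r} and {soc!r}"
                )
            pt_to_hlt[pt] = hlt
            hlt_to_soc[hlt] = soc
        if n_rows == 0:
            raise ValueError("empty hierarchy file")
        return cls(pt_to_hlt, hlt_to_soc)

    def term_at(self, pt: str, level: str) -> str | None:
        hlt = self.pt_to_hlt.get(pt)
        if hlt is None:
            return None
        return hlt if level == "HLT" else self.hlt_to_soc.get(hlt)


@dataclass
class ImmuneClassification:
    hlt: str
    label: str  # immune-related | immune-related-indirect | non-immune-related
    evidence_pts: list[str] = field(default_factory=list)


def load_watchlist(stream) -> frozenset[str]:
    """One PT per line; ``#`` starts a comment."""
    if isinstance(stream, str) and "\n" not in stream:
        with open(stream, encoding="utf-8") as fh:
            text = fh.read()
    elif isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    terms = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            terms.add(line)
    return frozenset(terms)


def rollup_events(
    report_pt_pairs: pd.DataFrame, meddra: MeddraMap, level: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map (primaryid, pt) pairs to (primaryid, term) pairs at HLT or SOC.

    Unique-report counting: a report contributes one pair per term even
    when several of its PTs land in the same term.  Returns the rolled
    pairs (columns primaryid, term) and the remainder of unmapped
    (primaryid, pt) pairs, which are reported, never silently dropped.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    pairs = report_pt_pairs[["primaryid", "pt"]].dropna().drop_duplicates()
    terms = pairs["pt"].map(lambda p: meddra.term_at(p, level))
    mapped = pairs[terms.notna()].assign(term=terms[terms.notna()])
    unmapped = pairs[terms.isna()].reset_index(drop=True)
    rolled = mapped[["primaryid", "term"]].drop_duplicates().reset_index(drop=True)
    return rolled, unmapped


def signals_at_level(
    cohort_ids: frozenset | set,
    rolled_pairs: pd.DataFrame,
    retained_ids: set,
    hyperparams_policy: str = "refit",
    pt_hyperparams: dp.GPSHyperparams | None = None,
    thresholds: dict = dp.DEFAULT_THRESHOLDS,
    min_cases_reported: int = 1,
    gps_seed: int = 0,
) -> pd.DataFrame:
    """Full four-statistic signal table on rolled-up (HLT/SOC) pairs.

    ``hyperparams_policy='refit'`` (default) refits the MGPS prior on
    the aggregated-table ensemble, since aggregation changes the count
    distribution; ``'reuse'`` applies the PT-level prior unchanged.
    """
    if hyperparams_policy not in ("refit", "reuse"):
        raise ValueError("hyperparams_policy must be 'refit' or 'reuse'")
    pairs = rolled_pairs.rename(columns={"term": "pt"})
    if hyperparams_policy == "reuse":
        if pt_hyperparams is None:
            raise ValueError("policy='reuse' requires pt_hyperparams")
        hp = pt_hyperparams
    else:
        hp = None
    return dp.signal_table(
        cohort_ids, pairs, retained_ids,
        hyperparams=hp, thresholds=thresholds,
        min_cases_reported=min_cases_reported, gps_seed=gps_seed,
    )


def member_pts(
    hlt_signals: pd.DataFrame,
    pt_signals: pd.DataFrame,
    meddra: MeddraMap,
    confirmed_only: bool = True,
) -> dict[str, list[str]]:
    """Significant member PTs per HLT, from the PT-level signal table."""
    pts = pt_signals
    if confirmed_only and "confirmed" in pts.columns:
        pts = pts[pts["confirmed"]]
    out: dict[str, list[str]] = {}
    for pt in pts["event_term"]:
        hlt = meddra.pt_to_hlt.get(pt)
        if hlt is not None:
            out.setdefault(hlt, []).append(pt)
    return {h: sorted(v) for h, v in out.items()}


def classify_immune(
    hlt_terms: list[str],
    significant_pts_by_hlt: dict[str, list[str]],
    direct_watchlist: frozenset[str],
    indirect_watchlist: frozenset[str],
) -> list[ImmuneClassification]:
    """Label each HLT by its significant member PTs against the watchlists.

    Deterministic and order-independent: evidence lists are sorted.
    """
    out = []
    for hlt in hlt_terms:
        pts = set(significant_pts_by_hlt.get(hlt, []))
        direct = sorted(pts & direct_watchlist)
        indirect = sorted(pts & indirect_watchlist)
        if direct:
            out.append(ImmuneClassification(hlt, "immune-related", direct))
        elif indirect:
            out.append(ImmuneClassification(hlt, "immune-related-indirect", indirect))
        else:
            out.append(ImmuneClassification(hlt, "non-immune-related", []))
    return out


def classification_frame(classifications: list[ImmuneClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"hlt": c.hlt, "label": c.label, "evidence_pts": ";".join(c.evidence_pts)}
            for c in classifications
        ]
    )
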