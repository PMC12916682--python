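"""Drug–event contingency tables and the four disproportionality statistics.

For each drug–event pair the 2×2 table over deduplicated reports is

    ==============  =============  ==============
                    event          no event
    ==============  =============  ==============
    target drug     a              b
    other drugs     c              d
    ==============  =============  ==============

with N = a+b+c+d and expected count E = (a+b)(a+c)/N under independence.

Four statistics are computed per pair:

* ROR  — reporting odds ratio ad/bc with a Woolf 95% CI;
* PRR  — proportional reporting ratio with a Yates-corrected χ²;
* IC   — the BCPNN information component log2[(a+0.5)/(E+0.5)] with the
  closed-form lower 2.5% credibility bound IC025;
* EBGM — the empirical-Bayes geometric mean of the observed/expected
  ratio under a two-component gamma mixture prior (MGPS) whose five
  hyperparameters are fit by maximizing the negative-binomial marginal
  likelihood over all pairs, with EBGM05 the posterior 5th percentile.

A *confirmed* signal passes the frequentist screen (ROR criterion or
PRR criterion) and both Bayesian gates (EBGM05 > 2 and IC025 > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

#: default signal thresholds (the study's values)
DEFAULT_THRESHOLDS = {
    "ror_ci_lo": 1.0,
    "min_cases": 3,
    "prr_min": 2.0,
    "chi2_min": 4.0,
    "ebgm05_min": 2.0,
    "ic025_min": 0.0,
}

#: canonical MGPS prior start point (alpha1, beta1, alpha2, beta2, P)
GPS_CANONICAL_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class ContingencyTable:
    """a/b/c/d counts for one drug–event pair over deduplicated reports."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the expected count under independence."""
        n = self.n
        if n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / n


@dataclass(frozen=True)
class GPSHyperparams:
    """Five-parameter gamma-mixture prior for the relative reporting rate."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    P: float
    loglik: float = float("nan")

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")
        if not (0.0 < self.P < 1.0):
            raise ValueError("mixture weight P must lie in (0, 1)")

    @property
    def prior_mean(self) -> float:
        return self.P * self.alpha1 / self.beta1 + (1 - self.P) * self.alpha2 / self.beta2


def build_contingency(
    cohort_ids: frozenset | set,
    reac: pd.DataFrame,
    retained_ids: set,
    event_term: str,
) -> ContingencyTable:
    """2×2 table for one (cohort, event term) pair, counted per report.

    A report contributes at most one count regardless of duplicated PT
    rows.  The background N is all retained reports.
    """
    rr = reac[reac["primaryid"].isin(retained_ids)]
    event_ids = set(rr.loc[rr["pt"] == event_term, "primaryid"])
    cohort = set(cohort_ids) & set(retained_ids)
    a = len(cohort & event_ids)
    b = len(cohort) - a
    c = len(event_ids) - a
    d = len(retained_ids) - a - b - c
    return ContingencyTable(a, b, c, d)


def contingency_frame(
    cohort_ids: frozenset | set,
    reac: pd.DataFrame,
    retained_ids: set,
) -> pd.DataFrame:
    """All drug–event 2×2 tables for one cohort, vectorized over PTs.

    Returns a frame indexed by event term with columns a, b, c, d, E.
    """
    rr = reac[reac["primaryid"].isin(retained_ids) & reac["pt"].notna()]
    pairs = rr[["primaryid", "pt"]].drop_duplicates()
    n_total = len(retained_ids)
    in_cohort = pairs["primaryid"].isin(set(cohort_ids))
    a = pairs[in_cohort].groupby("pt").size()
    event_total = pairs.groupby("pt").size()
    df = pd.DataFrame({"a": a.reindex(event_total.index, fill_value=0),
                       "event_total": event_total})
    n_cohort = len(set(cohort_ids) & set(retained_ids))
    df["b"] = n_cohort - df["a"]
    df["c"] = df["event_total"] - df["a"]
    df["d"] = n_total - n_cohort - df["c"]
    df["E"] = (df["a"] + df["b"]) * (df["a"] + df["c"]) / n_total
    df.index.name = "event_term"
    return df[["a", "b", "c", "d", "E"]].astype({"a": int, "b": int, "c": int, "d": int})


def _corrected_cells(t: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """Haldane–Anscombe +0.5 correction when any cell is zero."""
    cells = (t.a, t.b, t.c, t.d)
    if min(cells) == 0:
        return tuple(x + 0.5 for x in cells) + (True,)
    return tuple(float(x) for x in cells) + (False,)


def compute_ror(
    table: ContingencyTable, thresholds: dict = DEFAULT_THRESHOLDS
) -> tuple[float, float, float, bool, bool]:
    """ROR with Woolf 95% CI; returns (ror, lo95, hi95, significant, corrected).

    Significance requires the CI lower bound above 1 *and* at least 3
    target-drug cases.  Zero cells get the +0.5 continuity correction
    and the result is flagged corrected.
    """
    a, b, c, d, corrected = _corrected_cells(table)
    ror = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(ror) - 1.96 * se))
    hi = float(np.exp(np.log(ror) + 1.96 * se))
    sig = (lo > thresholds["ror_ci_lo"]) and (table.a >= thresholds["min_cases"])
    return float(ror), lo, hi, bool(sig), corrected


def compute_prr(
    table: ContingencyTable, thresholds: dict = DEFAULT_THRESHOLDS
) -> tuple[float, float, bool, bool]:
    """PRR and Yates-corrected χ²; returns (prr, chi2, significant, corrected).

    chi2 = N(|ad−bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)].  The PRR is
    undefined when no comparator report carries the event (c = 0); the
    +0.5 correction is then applied to all four cells and flagged.
    """
    if table.c == 0 or (table.a + table.b) == 0:
        a, b, c, d = (x + 0.5 for x in (table.a, table.b, table.c, table.d))
        corrected = True
    else:
        a, b, c, d = map(float, (table.a, table.b, table.c, table.d))
        corrected = False
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = num / den if den > 0 else float("nan")
    sig = (
        prr >= thresholds["prr_min"]
        and chi2 >= thresholds["chi2_min"]
        and table.a >= thresholds["min_cases"]
    )
    return float(prr), float(chi2), bool(sig), corrected


def compute_ic(
    table: ContingencyTable, thresholds: dict = DEFAULT_THRESHOLDS
) -> tuple[float, float, bool]:
    """BCPNN information component; returns (ic, ic025, significant).

    ic = log2[(a+0.5)/(E+0.5)]; the lower 2.5% credibility bound uses
    the closed-form approximation
    ic025 = ic − 3.3(a+0.5)^(−1/2) − 2.0(a+0.5)^(−3/2).
    """
    a = table.a
    e = table.expected
    ic = float(np.log2((a + 0.5) / (e + 0.5)))
    ic025 = float(ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5)
    return ic, ic025, bool(ic025 > thresholds["ic025_min"])


# ---------------------------------------------------------------------------
# MGPS: marginal-likelihood fit and posterior summaries
# ---------------------------------------------------------------------------

def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """log NegBin(a; alpha, beta/(beta+E)) — the gamma-Poisson marginal."""
    p = beta / (beta + e)
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1)
        + alpha * np.log(p)
        + a * np.log1p(-p)
    )


def gps_marginal_loglik(
    a: np.ndarray, e: np.ndarray, hp: GPSHyperparams | tuple
) -> float:
    """Σ log of the two-component negative-binomial mixture likelihood."""
    if isinstance(hp, GPSHyperparams):
        a1, b1, a2, b2, p = hp.alpha1, hp.beta1, hp.alpha2, hp.beta2, hp.P
    else:
        a1, b1, a2, b2, p = hp
    l1 = _nb_logpmf(a, e, a1, b1) + np.log(p)
    l2 = _nb_logpmf(a, e, a2, b2) + np.log1p(-p)
    return float(np.sum(np.logaddexp(l1, l2)))


def _theta_to_params(theta: np.ndarray) -> tuple[float, float, float, float, float]:
    a1, b1, a2, b2 = np.exp(np.clip(theta[:4], -20, 20))
    p = special.expit(np.clip(theta[4], -30, 30))
    return float(a1), float(b1), float(a2), float(b2), float(p)


def fit_gps(
    tables: pd.DataFrame,
    n_starts: int = 5,
    seed: int = 0,
    min_tables: int = 50,
) -> GPSHyperparams:
    """Fit the five MGPS hyperparameters by marginal-likelihood maximization.

    Parameters
    ----------
    tables
        Frame with columns ``a`` and ``E`` (one row per drug–event
        pair), e.g. from :func:`contingency_frame`.
    n_starts
        Nelder–Mead restarts: the canonical start (0.2, 0.1, 2.0, 4.0,
        1/3) plus seeded jitters; the best attained likelihood wins.

    Notes
    -----
    Optimization is derivative-free on log/logit-transformed parameters
    so the positivity and (0,1) constraints hold by construction.  No
    count squashing is applied — ensembles here are desk-scale.
    """
    df = tables[tables["E"] > 0]
    if len(df) < min_tables:
        warnings.warn(
            f"only {len(df)} tables with E>0; MGPS hyperparameter fit may be unstable",
            stacklevel=2,
        )
    a = df["a"].to_numpy(dtype=float)
    e = df["E"].to_numpy(dtype=float)
    if len(a) == 0:
        raise ValueError("no tables with positive expected count; cannot fit prior")

    def neg_ll(theta: np.ndarray) -> float:
        ll = gps_marginal_loglik(a, e, _theta_to_params(theta))
        return -ll if np.isfinite(ll) else 1e300

    a1, b1, a2, b2, p = GPS_CANONICAL_START
    base = np.array([np.log(a1), np.log(b1), np.log(a2), np.log(b2), special.logit(p)])
    rng = np.random.default_rng(seed)
    starts = [base] + [base + rng.normal(0, 0.7, size=5) for _ in range(n_starts - 1)]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e299:
        raise RuntimeError(
            f"MGPS fit failed: non-finite likelihood at all {len(starts)} starts "
            f"(n={len(a)}, mean a={a.mean():.3f}, mean E={e.mean():.3f})"
        )
    pa1, pb1, pa2, pb2, pp = _theta_to_params(best.x)
    hp = GPSHyperparams(pa1, pb1, pa2, pb2, pp, loglik=-float(best.fun))
    if abs(np.log(pa1 / pb1) - np.log(pa2 / pb2)) < 1e-3:
        warnings.warn("MGPS mixture components have merged (degenerate fit)", stacklevel=2)
    return hp


def _posterior_mixture(a: int, e: float, hp: GPSHyperparams):
    """Posterior over the relative reporting rate: weights and gamma params."""
    arr_a = np.array([float(a)])
    arr_e = np.array([float(e)])
    l1 = _nb_logpmf(arr_a, arr_e, hp.alpha1, hp.beta1)[0] + np.log(hp.P)
    l2 = _nb_logpmf(arr_a, arr_e, hp.alpha2, hp.beta2)[0] + np.log1p(-hp.P)
    qn = float(np.exp(l1 - np.logaddexp(l1, l2)))
    return qn, (hp.alpha1 + a, hp.beta1 + e), (hp.alpha2 + a, hp.beta2 + e)


def posterior_cdf(x: float, a: int, e: float, hp: GPSHyperparams) -> float:
    qn, (s1, r1), (s2, r2) = _posterior_mixture(a, e, hp)
    return qn * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - qn) * stats.gamma.cdf(
        x, s2, scale=1 / r2
    )


def compute_ebgm(
    table: ContingencyTable,
    hp: GPSHyperparams,
    thresholds: dict = DEFAULT_THRESHOLDS,
) -> tuple[float, float, bool]:
    """EBGM and its posterior 5th percentile; returns (ebgm, ebgm05, significant).

    The posterior is the gamma mixture Qn·Γ(α1+a, β1+E) +
    (1−Qn)·Γ(α2+a, β2+E); EBGM = exp E[ln λ] via the digamma function,
    and EBGM05 solves CDF(x) = 0.05 by bracketed root-finding.
    """
    a, e = table.a, table.expected
    qn, (s1, r1), (s2, r2) = _posterior_mixture(a, e, hp)
    log_geo = qn * (special.digamma(s1) - np.log(r1)) + (1 - qn) * (
        special.digamma(s2) - np.log(r2)
    )
    ebgm = float(np.exp(log_geo))

    def f(x: float) -> float:
        return posterior_cdf(x, a, e, hp) - 0.05

    lo, hi = 1e-12, max(ebgm, 1.0)
    it = 0
    while f(hi) < 0:
        hi *= 2.0
        it += 1
        if it > 200:
            raise RuntimeError(
                f"EBGM05 bracket expansion failed: cdf({hi:.3g})={f(hi)+0.05:.3g} "
                f"(a={a}, E={e:.4g})"
            )
    ebgm05 = float(optimize.brentq(f, lo, hi, xtol=1e-8))
    return ebgm, ebgm05, bool(ebgm05 > thresholds["ebgm05_min"])


def evaluate_signal(
    ror_sig: bool, prr_sig: bool, ebgm_sig: bool, ic_sig: bool
) -> bool:
    """Combined criterion: (ROR or PRR screen) and both Bayesian gates."""
    return (ror_sig or prr_sig) and ebgm_sig and ic_sig


def signal_table(
    cohort_ids: frozenset | set,
    reac: pd.DataFrame,
    retained_ids: set,
    hyperparams: GPSHyperparams | None = None,
    thresholds: dict = DEFAULT_THRESHOLDS,
    min_cases_reported: int = 1,
    gps_seed: int = 0,
) -> pd.DataFrame:
    """All four statistics for every event term reported with the cohort.

    When ``hyperparams`` is None the MGPS prior is fit on this cohort's
    full table ensemble first.  Rows are sorted by descending case
    count then term for deterministic output.
    """
    columns = [
        "event_term", "a", "E", "ROR", "ROR_lo95", "ROR_hi95", "PRR", "chi2",
        "IC", "IC025", "EBGM", "EBGM05", "ror_sig", "prr_sig", "ic_sig",
        "ebgm_sig", "confirmed",
    ]
    tables = contingency_frame(cohort_ids, reac, retained_ids)
    if not (tables["E"] > 0).any():
        # empty cohort (or no events at all): nothing is testable
        return pd.DataFrame(columns=columns)
    if hyperparams is None:
        hyperparams = fit_gps(tables, seed=gps_seed)
    rows = []
    sel = tables[tables["a"] >= min_cases_reported]
    for term, r in sel.iterrows():
        t = ContingencyTable(int(r["a"]), int(r["b"]), int(r["c"]), int(r["d"]))
        ror, lo, hi, ror_sig, _ = compute_ror(t, thresholds)
        prr, chi2, prr_sig, _ = compute_prr(t, thresholds)
        ic, ic025, ic_sig = compute_ic(t, thresholds)
        ebgm, ebgm05, ebgm_sig = compute_ebgm(t, hyperparams, thresholds)
        rows.append(
            {
                "event_term": term, "a": t.a, "E": t.expected,
                "ROR": ror, "ROR_lo95": lo, "ROR_hi95": hi,
                "PRR": prr, "chi2": chi2, "IC": ic, "IC025": ic025,
                "EBGM": ebgm, "EBGM05": ebgm05,
                "ror_sig": ror_sig, "prr_sig": prr_sig,
                "ic_sig": ic_sig, "ebgm_sig": ebgm_sig,
                "confirmed": evaluate_signal(ror_sig, prr_sig, ebgm_sig, ic_sig),
            }
        )
    out = pd.DataFrame(rows, columns=columns)
    if not out.empty:
        out = out.sort_values(["a", "event_term"], ascending=[False, True]).reset_index(
            drop=True
        )
    return out
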