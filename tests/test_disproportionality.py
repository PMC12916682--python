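"""The four disproportionality statistics against closed-form and
simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from faerspv import disproportionality as dp
from faerspv.disproportionality import (
    ContingencyTable,
    GPSHyperparams,
    build_contingency,
    compute_ebgm,
    compute_ic,
    compute_prr,
    compute_ror,
    contingency_frame,
    evaluate_signal,
    fit_gps,
    gps_marginal_loglik,
)

WORKED = ContingencyTable(5, 95, 100, 9800)  # the hand-worked 2×2


class TestContingency:
    def test_expected_count(self):
        assert WORKED.expected == pytest.approx(100 * 105 / 10000)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_set_arithmetic_example(self):
        reac = pd.DataFrame(
            {"primaryid": ["2", "3", "7"], "pt": ["X"] * 3}, dtype="string"
        )
        t = build_contingency({"1", "2", "3"}, reac, {str(i) for i in range(1, 11)}, "X")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 6)

    def test_duplicate_pt_rows_count_once(self):
        reac = pd.DataFrame(
            {"primaryid": ["1", "1", "2"], "pt": ["X", "X", "X"]}, dtype="string"
        )
        t = build_contingency({"1"}, reac, {"1", "2", "3"}, "X")
        assert (t.a, t.c) == (1, 1)

    def test_absent_event_term_gives_empty_margin(self):
        reac = pd.DataFrame({"primaryid": ["1"], "pt": ["X"]}, dtype="string")
        t = build_contingency({"1"}, reac, {"1", "2"}, "NOT A TERM")
        assert (t.a, t.c) == (0, 0)

    def test_frame_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        ids = [str(i) for i in range(1000)]
        reac = pd.DataFrame(
            {
                "primaryid": rng.choice(ids, size=3000),
                "pt": rng.choice(["P1", "P2", "P3", "P4"], size=3000),
            },
            dtype="string",
        )
        cohort = set(ids[:200])
        frame = contingency_frame(cohort, reac, set(ids))
        for term in ["P1", "P2", "P3", "P4"]:
            ev = set(reac.loc[reac["pt"] == term, "primaryid"])
            a = len(ev & cohort)
            assert frame.loc[term, "a"] == a
            assert frame.loc[term, "c"] == len(ev) - a
            assert frame.loc[term, "a"] + frame.loc[term, "b"] == len(cohort)
            assert frame.loc[term, ["a", "b", "c", "d"]].sum() == 1000


class TestROR:
    def test_worked_example_to_4_significant_figures(self):
        ror, lo, hi, sig, corrected = compute_ror(WORKED)
        assert ror == pytest.approx(5.158, rel=5e-4)
        assert lo == pytest.approx(2.054, rel=5e-4)
        assert hi == pytest.approx(12.95, rel=5e-4)
        assert sig and not corrected

    def test_proportional_rows_give_unity(self):
        ror, *_ = compute_ror(ContingencyTable(1, 9, 10, 90))
        assert ror == pytest.approx(1.0)

    def test_case_count_gate_blocks_small_a(self):
        # strong disproportion but only 2 cases
        ror, lo, hi, sig, _ = compute_ror(ContingencyTable(2, 8, 10, 9980))
        assert lo > 1 and not sig

    def test_zero_cell_gets_haldane_correction(self):
        ror, lo, hi, sig, corrected = compute_ror(ContingencyTable(5, 95, 0, 9900))
        assert corrected and np.isfinite(ror) and np.isfinite(hi)


class TestPRR:
    def test_worked_example_to_4_significant_figures(self):
        prr, chi2, sig, _ = compute_prr(WORKED)
        assert prr == pytest.approx(4.950, rel=5e-4)
        assert chi2 == pytest.approx(11.57, rel=5e-4)
        assert sig

    def test_no_disproportion(self):
        prr, chi2, sig, _ = compute_prr(ContingencyTable(1, 9, 10, 90))
        assert prr == pytest.approx(1.0) and not sig

    def test_threshold_gate(self):
        prr, chi2, sig, _ = compute_prr(ContingencyTable(3, 97, 200, 9700))
        assert prr < 2 and not sig

    def test_zero_comparator_event_corrected(self):
        prr, chi2, sig, corrected = compute_prr(ContingencyTable(5, 95, 0, 9900))
        assert corrected and np.isfinite(prr)


class TestIC:
    def test_worked_example(self):
        ic, ic025, sig = compute_ic(WORKED)
        assert ic == pytest.approx(1.827, rel=5e-4)
        assert ic025 == pytest.approx(0.265, abs=5e-4)
        assert sig

    def test_independence_is_zero(self):
        ic, *_ = compute_ic(ContingencyTable(1, 9, 10, 90))  # E = 1 exactly
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_deficit_case_negative(self):
        ic, ic025, sig = compute_ic(ContingencyTable(0, 100, 100, 9900))
        assert ic < 0 and not sig


class TestCombinedCriterion:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((True, True, True, True), True),
            ((True, False, True, True), True),   # ROR alone screens
            ((False, True, True, True), True),   # PRR alone screens
            ((True, True, False, True), False),  # EBGM05 gate
            ((True, True, True, False), False),  # IC025 gate
            ((False, False, True, True), False),  # no screen
        ],
    )
    def test_conjunction_of_screen_and_bayesian_gates(self, flags, expected):
        assert evaluate_signal(*flags) is expected


@pytest.mark.parametrize("b,c,d", [(95, 100, 9800), (10, 50, 500)])
def test_ror_and_prr_nondecreasing_in_a(b, c, d):
    rors, prrs = [], []
    for a in range(1, 30):
        rors.append(compute_ror(ContingencyTable(a, b, c, d))[0])
        prrs.append(compute_prr(ContingencyTable(a, b, c, d))[0])
    assert all(x2 >= x1 for x1, x2 in zip(rors, rors[1:]))
    assert all(x2 >= x1 for x1, x2 in zip(prrs, prrs[1:]))


def test_exact_independence_margins_near_zero_ic():
    # a·d = b·c with a ≥ 100: smoothing perturbs IC by < 0.01
    t = ContingencyTable(100, 900, 1000, 9000)
    ror, *_ = compute_ror(t)
    prr, *_ = compute_prr(t)
    ic, *_ = compute_ic(t)
    assert ror == pytest.approx(1.0) and prr == pytest.approx(1.0)
    assert abs(ic) < 0.01


# ---------------------------------------------------------------------------
# MGPS
# ---------------------------------------------------------------------------

TRUE_PRIOR = GPSHyperparams(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def simulate_from_prior(hp: GPSHyperparams, n: int, seed: int) -> pd.DataFrame:
    """Draw (a, E) cells from the gamma-Poisson mixture — the oracle
    generating process the fitter should recover."""
    rng = np.random.default_rng(seed)
    e = np.exp(rng.normal(1.0, 1.0, size=n))
    comp = rng.random(n) < hp.P
    lam = np.where(
        comp,
        rng.gamma(hp.alpha1, 1 / hp.beta1, size=n),
        rng.gamma(hp.alpha2, 1 / hp.beta2, size=n),
    )
    a = rng.poisson(lam * e)
    return pd.DataFrame({"a": a, "E": e})


class TestGPSFit:
    def test_likelihood_dominance_over_generating_prior(self):
        cells = simulate_from_prior(TRUE_PRIOR, 5000, seed=11)
        fit = fit_gps(cells, seed=11)
        truth_ll = gps_marginal_loglik(
            cells["a"].to_numpy(float), cells["E"].to_numpy(float), TRUE_PRIOR
        )
        assert fit.loglik >= truth_ll - 1.0

    def test_null_data_concentrates_prior_near_one(self):
        rng = np.random.default_rng(5)
        e = np.exp(rng.normal(1.0, 1.0, size=4000))
        cells = pd.DataFrame({"a": rng.poisson(e), "E": e})  # λ = 1 exactly
        fit = fit_gps(cells, seed=5)
        assert 0.5 <= fit.prior_mean <= 2.0

    def test_single_component_truth_nested_model_equivalence(self):
        # truth is one gamma (shape 1.5, rate 1.5); the 5-parameter
        # mixture must not beat (or trail) the 2-parameter fit by > 2
        rng = np.random.default_rng(9)
        n = 4000
        e = np.exp(rng.normal(1.0, 0.8, size=n))
        lam = rng.gamma(1.5, 1 / 1.5, size=n)
        a = rng.poisson(lam * e)
        cells = pd.DataFrame({"a": a, "E": e})
        fit = fit_gps(cells, seed=9)

        from scipy.optimize import minimize

        def single_nll(theta):
            al, be = np.exp(theta)
            return -float(np.sum(dp._nb_logpmf(a.astype(float), e, al, be)))

        res = minimize(single_nll, [0.0, 0.0], method="Nelder-Mead")
        single_ll = -res.fun
        assert fit.loglik >= single_ll - 1e-3  # mixture nests the single gamma
        assert abs(fit.loglik - single_ll) <= 2.0

    def test_few_tables_warns(self):
        cells = simulate_from_prior(TRUE_PRIOR, 10, seed=2)
        with pytest.warns(UserWarning, match="unstable"):
            fit_gps(cells, seed=2)


class TestEBGM:
    def test_degenerate_prior_matches_digamma_closed_form(self):
        # P→1 via two identical components: posterior is Gamma(6, 2.05)
        hp = GPSHyperparams(1.0, 1.0, 1.0, 1.0, 0.5)
        ebgm, ebgm05, sig = compute_ebgm(WORKED, hp)
        e = WORKED.expected
        assert ebgm == pytest.approx(np.exp(special.digamma(6) - np.log(1 + e)), abs=1e-6)
        assert ebgm05 == pytest.approx(stats.gamma.ppf(0.05, 6) / (1 + e), abs=1e-6)
        assert ebgm == pytest.approx(2.687, rel=5e-4)
        assert ebgm05 == pytest.approx(1.275, rel=5e-4)
        assert not sig

    def test_observed_equals_expected_stays_near_one(self):
        hp = GPSHyperparams(1.0, 1.0, 1.0, 1.0, 0.5)  # diffuse prior, mean 1
        t = ContingencyTable(20, 180, 980, 8820)  # a = 20 = E exactly
        assert t.expected == pytest.approx(t.a)
        ebgm, *_ = compute_ebgm(t, hp)
        assert 0.8 <= ebgm <= 1.3

    def test_shrinkage_vanishes_at_large_counts(self):
        # a/E = 5 fixed, a = 500: shrinkage < 5%
        hp = GPSHyperparams(*dp.GPS_CANONICAL_START)
        t = ContingencyTable(500, 4500, 1500, 93500)  # E = 100 exactly
        assert t.a / t.expected == pytest.approx(5.0, rel=0.01)
        ebgm, *_ = compute_ebgm(t, hp)
        assert ebgm == pytest.approx(5.0, rel=0.05)

    def test_ebgm05_matches_monte_carlo_posterior_quantile(self):
        rng = np.random.default_rng(17)
        hp = GPSHyperparams(0.7, 0.6, 2.0, 1.5, 0.4)
        for _ in range(5):
            a = int(rng.integers(0, 25))
            b = int(rng.integers(50, 500))
            c = int(rng.integers(20, 400))
            d = int(rng.integers(5000, 50000))
            t = ContingencyTable(a, b, c, d)
            qn, (s1, r1), (s2, r2) = dp._posterior_mixture(a, t.expected, hp)
            n_draw = 100_000
            draws = np.where(
                rng.random(n_draw) < qn,
                rng.gamma(s1, 1 / r1, n_draw),
                rng.gamma(s2, 1 / r2, n_draw),
            )
            _, ebgm05, _ = compute_ebgm(t, hp)
            assert ebgm05 == pytest.approx(np.quantile(draws, 0.05), abs=0.02)

    def test_ebgm_between_prior_mean_side_and_raw_ratio(self):
        """Shrinkage: EBGM lies between the prior geometric mean and the
        raw a/E, checked over 1,000 random tables."""
        cells = simulate_from_prior(TRUE_PRIOR, 1000, seed=23)
        hp = fit_gps(cells, seed=23)
        prior_geo = np.exp(
            hp.P * (special.digamma(hp.alpha1) - np.log(hp.beta1))
            + (1 - hp.P) * (special.digamma(hp.alpha2) - np.log(hp.beta2))
        )
        for a, e in cells.itertuples(index=False):
            qn, (s1, r1), (s2, r2) = dp._posterior_mixture(int(a), float(e), hp)
            log_geo = qn * (special.digamma(s1) - np.log(r1)) + (1 - qn) * (
                special.digamma(s2) - np.log(r2)
            )
            ebgm = float(np.exp(log_geo))
            lo = min(prior_geo, a / e)
            hi = max(prior_geo, a / e)
            assert lo * 0.95 <= ebgm <= hi * 1.05 or abs(ebgm - a / e) < 0.5
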