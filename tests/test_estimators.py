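import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cismr.estimators import (
    EstimationError,
    FitConfig,
    fit_instrument_set,
    gls_fit,
    orient_for_egger,
    prune_instruments,
    run_cis_mr,
)
from cismr.instruments import InstrumentSet, compute_f_stats
from cismr.sumstats import LDMatrix, VariantKey


def make_iset(bx, by, sy, r=None, sx=None):
    bx, by, sy = map(np.asarray, (bx, by, sy))
    k = len(bx)
    keys = [VariantKey("1", 1000 + i, "A", "G") for i in range(k)]
    r = np.eye(k) if r is None else np.asarray(r)
    sx = np.full(k, 0.01) if sx is None else np.asarray(sx)
    return InstrumentSet(
        "exp", "out", keys, bx, sx, by, sy, compute_f_stats(bx, sx), LDMatrix(keys, r, 100)
    )


def random_correlation(rng, k):
    a = rng.standard_normal((k, k + 3))
    c = a @ a.T
    d = np.sqrt(np.diag(c))
    r = c / np.outer(d, d)
    r = 0.95 * r + 0.05 * np.eye(k)
    np.fill_diagonal(r, 1.0)
    return r


class TestGLSFit:
    def test_uncorrelated_ivw_closed_form(self):
        fit = gls_fit([0.2, 0.4], [0.06, 0.12], [0.1, 0.1], np.eye(2))
        assert fit.slope == pytest.approx(0.3)
        assert fit.Q == pytest.approx(0.0, abs=1e-12)
        assert fit.slope_se == pytest.approx(np.sqrt(1 / 20))

    def test_uncorrelated_ivw_with_heterogeneity(self):
        fit = gls_fit([0.2, 0.4], [0.08, 0.12], [0.1, 0.1], np.eye(2))
        assert fit.slope == pytest.approx(0.32)
        assert fit.Q == pytest.approx(0.032)

    def test_egger_recovers_exact_linear_data(self):
        bx = np.array([0.2, 0.3, 0.5])
        by = 0.05 + 0.3 * bx
        fit = gls_fit(bx, by, [0.1] * 3, np.eye(3), with_intercept=True)
        assert fit.intercept == pytest.approx(0.05)
        assert fit.slope == pytest.approx(0.3)
        assert fit.Q == pytest.approx(0.0, abs=1e-12)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_identity_ld_matches_textbook_ivw_ratio(self, data):
        k = data.draw(st.integers(2, 6))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        bx = rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k)
        by = rng.normal(0, 0.1, k)
        sy = rng.uniform(0.02, 0.3, k)
        fit = gls_fit(bx, by, sy, np.eye(k))
        w = 1 / sy**2
        textbook = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert fit.slope == pytest.approx(textbook, abs=1e-10)
        assert fit.slope_se * np.sqrt(1 / fit.phi) == pytest.approx(
            np.sqrt(1 / np.sum(w * bx**2)), abs=1e-10
        )

    @given(c=st.floats(min_value=0.1, max_value=10.0), seed=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        k = 5
        bx = rng.uniform(0.1, 0.5, k)
        by = rng.normal(0, 0.1, k)
        sy = rng.uniform(0.05, 0.2, k)
        r = random_correlation(rng, k)
        a = gls_fit(bx, by, sy, r)
        b = gls_fit(c * bx, by, sy, r)
        assert b.slope == pytest.approx(a.slope / c, rel=1e-9)
        assert b.Q == pytest.approx(a.Q, rel=1e-9)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(EstimationError, match="at least"):
            gls_fit([0.2], [0.1], [0.1], np.eye(1))
        with pytest.raises(EstimationError, match="at least"):
            gls_fit([0.2, 0.3], [0.1, 0.1], [0.1, 0.1], np.eye(2), with_intercept=True)

    def test_singular_omega_advises_ridge(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(EstimationError, match="ridge"):
            gls_fit([0.2, 0.4], [0.1, 0.1], [0.1, 0.1], r)

    def test_phi_floor_at_one(self):
        bx = np.array([0.2, 0.3, 0.5])
        fit = gls_fit(bx, 0.3 * bx, [0.1] * 3, np.eye(3))
        assert fit.phi == 1.0


class TestOrientation:
    def test_all_positive_is_identity(self):
        iset = make_iset([0.2, 0.4], [0.1, 0.1], [0.1, 0.1])
        assert orient_for_egger(iset) is iset

    def test_idempotent(self):
        iset = make_iset([-0.2, 0.4, -0.1], [0.1, 0.1, 0.05], [0.1, 0.1, 0.1])
        once = orient_for_egger(iset)
        twice = orient_for_egger(once)
        assert np.array_equal(once.bx, twice.bx)
        assert np.array_equal(once.ld.r, twice.ld.r)
        assert (once.bx >= 0).all()

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_ivw_invariant_under_orientation(self, seed):
        rng = np.random.default_rng(seed)
        k = 5
        bx = rng.uniform(0.1, 0.5, k) * rng.choice([-1, 1], k)
        by = rng.normal(0, 0.1, k)
        sy = rng.uniform(0.05, 0.2, k)
        r = random_correlation(rng, k)
        iset = make_iset(bx, by, sy, r)
        a = fit_instrument_set(iset, with_intercept=False)
        b = fit_instrument_set(orient_for_egger(iset), with_intercept=False)
        assert b.slope == pytest.approx(a.slope, rel=1e-9)
        assert b.Q == pytest.approx(a.Q, rel=1e-9)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_single_variant_flip_leaves_estimates_unchanged(self, seed):
        # flipping one instrument's harmonized orientation (bx, by, LD signs)
        # must not move IVW or post-orientation Egger
        rng = np.random.default_rng(seed)
        k = 5
        bx = rng.uniform(0.1, 0.5, k)
        by = rng.normal(0, 0.1, k)
        sy = rng.uniform(0.05, 0.2, k)
        r = random_correlation(rng, k)
        j = int(rng.integers(0, k))
        s = np.ones(k)
        s[j] = -1
        a_ivw = gls_fit(bx, by, sy, r)
        b_ivw = gls_fit(s * bx, s * by, sy, r * np.outer(s, s))
        assert b_ivw.slope == pytest.approx(a_ivw.slope, rel=1e-9)
        iset_a = make_iset(bx, by, sy, r)
        iset_b = make_iset(s * bx, s * by, sy, r * np.outer(s, s))
        e_a = fit_instrument_set(orient_for_egger(iset_a), with_intercept=True)
        e_b = fit_instrument_set(orient_for_egger(iset_b), with_intercept=True)
        assert e_b.slope == pytest.approx(e_a.slope, rel=1e-9)
        assert e_b.intercept == pytest.approx(e_a.intercept, rel=1e-9)


class TestPruning:
    def test_perfect_fit_prunes_nothing(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        iset = make_iset(bx, 0.3 * bx, np.full(5, 0.1))
        kept, pruned = prune_instruments(iset, FitConfig())
        assert pruned == []
        assert kept.k == 5

    def test_symmetric_design_has_no_leverage_outliers(self):
        bx = np.array([0.2, 0.2, 0.2, 0.2])
        iset = make_iset(bx, 0.3 * bx, np.full(4, 0.1))
        fit = fit_instrument_set(iset, with_intercept=False)
        assert np.allclose(fit.leverage, fit.leverage[0])
        kept, pruned = prune_instruments(iset, FitConfig())
        assert pruned == []

    def test_constructed_outlier_is_pruned_exactly(self):
        # displace one point so its squared whitened residual is exactly 25:
        # with identity LD and sy=1, e = (I - H) d, so d = 5 / (1 - h_jj)
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        sy = np.ones(5)
        by = 0.3 * bx
        X = bx[:, None]
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        j = 2
        d = 5.0 / (1 - H[j, j])
        by_out = by.copy()
        by_out[j] += d
        iset = make_iset(bx, by_out, sy)
        kept, pruned = prune_instruments(iset, FitConfig())
        assert len(pruned) == 1
        assert pruned[0]["variant"] == iset.variants[j]
        assert pruned[0]["reason"] == "outlier"
        assert pruned[0]["value"] == pytest.approx(25.0, rel=1e-9)


class TestModelSelection:
    def test_egger_chosen_when_q_difference_large(self):
        # strong directional offset: IVW misfits, Egger fits exactly
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.5 + 0.3 * bx
        iset = make_iset(bx, by, np.full(5, 0.05))
        est = run_cis_mr(iset, FitConfig(outlier_chi2=1e9, leverage_multiplier=1e9))
        assert est.method == "Egger"
        assert est.Q_ivw - est.Q_egger > 3.84
        assert est.b0 == pytest.approx(0.5)
        assert est.alpha_hat == pytest.approx(0.3)

    def test_ivw_kept_when_q_difference_small(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.3 * bx
        iset = make_iset(bx, by, np.full(5, 0.05))
        est = run_cis_mr(iset)
        assert est.method == "IVW"

    def test_too_few_for_egger_reports_ivw_with_note(self):
        iset = make_iset([0.2, 0.4], [0.06, 0.12], [0.1, 0.1])
        est = run_cis_mr(iset)
        assert est.method == "IVW"
        assert est.Q_egger is None
        assert "Egger" in est.note

    def test_binary_outcome_reports_odds_ratio(self):
        bx = np.array([0.2, 0.3, 0.5])
        iset = make_iset(bx, 0.3 * bx, np.full(3, 0.1))
        est = run_cis_mr(iset, binary=True)
        assert est.odds_ratio == pytest.approx(np.exp(est.alpha_hat))
        assert est.or_ci_low == pytest.approx(np.exp(est.ci_low))

    def test_ci_brackets_estimate(self):
        bx = np.array([0.2, 0.3, 0.5, 0.1])
        rng = np.random.default_rng(3)
        iset = make_iset(bx, 0.3 * bx + rng.normal(0, 0.02, 4), np.full(4, 0.1))
        est = run_cis_mr(iset)
        assert est.ci_low <= est.alpha_hat <= est.ci_high
        assert est.ci_high - est.alpha_hat == pytest.approx(1.96 * est.alpha_se, rel=1e-3)


@given(seed=st.integers(0, 10**6))
@settings(max_examples=60, deadline=None)
def test_egger_q_never_exceeds_ivw_q(seed):
    # nested weighted least squares: adding an intercept cannot increase Q
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 9))
    bx = rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k)
    by = rng.normal(0, 0.2, k)
    sy = rng.uniform(0.05, 0.3, k)
    r = random_correlation(rng, k)
    iset = make_iset(bx, by, sy, r)
    ivw = fit_instrument_set(iset, with_intercept=False)
    egger = fit_instrument_set(orient_for_egger(iset), with_intercept=True)
    assert egger.Q <= ivw.Q + 1e-9
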