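"""Effect estimators: exactness, oracles, permutation and Holm behaviour."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from painrct.config import TrialConfig
from painrct.errors import InvalidArgumentError, WeakInstrumentError
from painrct.inference import (
    AnalysisSpec,
    binary_effect,
    cace_estimate,
    covariate_matrix,
    fast_linear_permutation_pvalues,
    holm_adjust,
    itt_estimate,
    permutation_pvalue,
)
from painrct.synthetic import generate_outcome_frame

SPEC = AnalysisSpec(outcome="y", adjust_covariates=False)


def _frame(y, allocated, exposed=None, **cols):
    n = len(y)
    base = {
        "y": np.asarray(y, float),
        "allocated": np.asarray(allocated, int),
        "exposed": np.asarray(exposed if exposed is not None else allocated, int),
    }
    base.update(cols)
    return pd.DataFrame(base)


def _pm1_residuals(rng, n, c=0.3):
    """Symmetric two-point residuals: MAD-scaled Huber weights stay at 1,
    so the robust fit coincides with ordinary least squares exactly."""
    signs = np.ones(n)
    signs[: n // 2] = -1
    rng.shuffle(signs)
    return c * signs


class TestItt:
    def test_noiseless_allocation_effect_recovered_exactly(self):
        alloc = np.array([0, 1] * 10)
        frame = _frame(0.5 * alloc + 1.0, alloc)
        spec = AnalysisSpec(outcome="y", adjust_covariates=False)
        est = itt_estimate(frame, spec)
        assert est.estimate == pytest.approx(0.5, abs=1e-8)

    def test_equals_ols_without_outliers(self, rng):
        n = 60
        alloc = rng.integers(0, 2, n)
        y = 1.0 + 0.4 * alloc + _pm1_residuals(rng, n)
        frame = _frame(y, alloc)
        spec = AnalysisSpec(outcome="y", adjust_covariates=False)
        est = itt_estimate(frame, spec)
        X = sm.add_constant(alloc.astype(float))
        ols = sm.OLS(y, X).fit().params[1]
        assert est.estimate == pytest.approx(ols, abs=1e-8)

    def test_unbiased_over_null_replicates(self):
        cfg = TrialConfig(n=40)
        cfg = cfg.replace(ground_truth=dataclasses.replace(cfg.ground_truth, complier_effect_r=0.0))
        ests = []
        for rep in range(200):
            frame = generate_outcome_frame(cfg, seed=1000 + rep)
            ests.append(itt_estimate(frame, AnalysisSpec(outcome="nnrf")).estimate)
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean()) < 3 * se


class TestCace:
    def test_full_compliance_reduces_to_itt(self, rng):
        n = 80
        alloc = rng.integers(0, 2, n)
        y = 0.7 * alloc + _pm1_residuals(rng, n)
        frame = _frame(y, alloc, exposed=alloc)
        spec = AnalysisSpec(outcome="y", adjust_covariates=False)
        assert cace_estimate(frame, spec).estimate == pytest.approx(
            itt_estimate(frame, spec).estimate, abs=1e-8
        )

    def test_matches_wald_ratio_without_covariates(self, rng):
        for rep in range(50):
            local = np.random.default_rng(rep)
            n = 60
            alloc = np.repeat([0, 1], n // 2)
            compliant = local.random(n) < 0.8
            exposed = (alloc == 1) & compliant
            y = local.normal(1.0, 0.6, n) - 0.4 * exposed
            frame = _frame(y, alloc, exposed=exposed.astype(int))
            est = cace_estimate(frame, AnalysisSpec(outcome="y", adjust_covariates=False))
            itt_diff = y[alloc == 1].mean() - y[alloc == 0].mean()
            rate_diff = exposed[alloc == 1].mean() - exposed[alloc == 0].mean()
            assert est.estimate == pytest.approx(itt_diff / rate_diff, abs=1e-8)

    def test_uninformative_instrument_rejected(self):
        frame = _frame(np.arange(20.0), [0, 1] * 10, exposed=np.zeros(20, int))
        with pytest.raises(WeakInstrumentError):
            cace_estimate(frame, AnalysisSpec(outcome="y", adjust_covariates=False))


class TestBinary:
    def _table_frame(self, e1, n1, e0, n0):
        y = np.concatenate([np.ones(e1), np.zeros(n1 - e1), np.ones(e0), np.zeros(n0 - e0)])
        alloc = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
        return _frame(y, alloc)

    def test_odds_ratio_matches_contingency_closed_form(self):
        frame = self._table_frame(10, 50, 5, 50)
        est = binary_effect(frame, AnalysisSpec(outcome="y", adjust_covariates=False))
        assert est.extra["odds_ratio"] == pytest.approx((10 * 45) / (5 * 40), rel=1e-6)
        assert est.extra["risk_ratio"] == pytest.approx((10 / 50) / (5 / 50), rel=1e-6)
        assert not est.extra["firth"]

    def test_identical_event_rates_give_unit_odds_ratio(self):
        frame = self._table_frame(8, 50, 8, 50)
        est = binary_effect(frame, AnalysisSpec(outcome="y", adjust_covariates=False))
        assert est.extra["odds_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_falls_back_to_firth(self):
        # all events in one arm: ML diverges, Firth stays finite
        frame = self._table_frame(10, 20, 0, 20)
        est = binary_effect(frame, AnalysisSpec(outcome="y", adjust_covariates=False))
        assert est.extra["firth"]
        assert np.isfinite(est.estimate)


class TestPermutation:
    def test_constant_outcome_gives_p_one(self):
        frame = _frame(np.ones(16), [0, 1] * 8)
        spec = AnalysisSpec(outcome="y", adjust_covariates=False, n_permutations=200)
        p = permutation_pvalue(frame, spec, itt_estimate)
        assert p == pytest.approx(1.0)

    def test_fast_path_matches_exhaustive_enumeration(self):
        """n = 8: compare the Monte-Carlo p with the exact permutation
        distribution enumerated over all assignments of 4 labels to 8 slots."""
        from itertools import combinations

        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 8)
        alloc = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)

        def stat(a):
            return abs(y[a == 1].mean() - y[a == 0].mean())

        t_obs = stat(alloc)
        stats_all = []
        for idx in combinations(range(8), 4):
            a = np.zeros(8)
            a[list(idx)] = 1
            stats_all.append(stat(a))
        exact = np.mean([s >= t_obs - 1e-12 for s in stats_all])

        p_mc = fast_linear_permutation_pvalues(
            y, alloc, None, n_permutations=100_000, rng=np.random.default_rng(4)
        )
        assert p_mc == pytest.approx(exact, abs=0.01)

    def test_fast_path_equals_full_refit_statistic(self, rng):
        """FWL residualisation reproduces the covariate-adjusted OLS
        allocation coefficient that a full refit would give."""
        n = 40
        alloc = rng.integers(0, 2, n).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 0.3 * alloc + cov @ [0.5, -0.2] + rng.normal(0, 1, n)
        Xfull = sm.add_constant(np.column_stack([alloc, cov]))
        beta_full = sm.OLS(y, Xfull).fit().params[1]
        Q, _ = np.linalg.qr(sm.add_constant(cov))
        my = y - Q @ (Q.T @ y)
        ma = alloc - Q @ (Q.T @ alloc)
        assert ma @ my / (ma @ ma) == pytest.approx(beta_full, abs=1e-10)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == [0.2]

    def test_stepdown_hand_computation(self):
        assert holm_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.04, 0.04])

    def test_adjusted_never_below_raw_and_capped(self, rng):
        p = rng.random(6)
        adj = holm_adjust(p)
        assert all(a >= r for a, r in zip(adj, p))
        assert all(a <= 1 for a in adj)
        # weak order preservation: smaller raw p never gets larger adjusted p
        for i in range(len(p)):
            for j in range(len(p)):
                if p[i] < p[j]:
                    assert adj[i] <= adj[j]

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            holm_adjust([])


def test_covariate_matrix_dummy_codes_categoricals():
    frame = pd.DataFrame(
        {"ga": [38.0, 39.0], "sex": ["male", "female"], "site": ["A", "A"]}
    )
    X = covariate_matrix(frame, ("ga", "sex", "site"))
    assert "ga" in X.columns
    assert any(c.startswith("sex_") for c in X.columns)
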