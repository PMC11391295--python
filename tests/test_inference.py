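"""Statistical layer: OLS vs normal-equations oracle, mixed-model behaviour,
lag t-test, Mann-Whitney spacing, questionnaire arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ritualsync import (
    fit_category_model,
    fit_network_model,
    fit_surrogate_contrast_model,
    holm_adjust,
    lag_t_test,
    spacing_comparison,
    summarize_questionnaire,
)
from ritualsync.inference import significance_stars


def pair_frame(categories, outcomes, node_distance=None, types=None, signal="posture"):
    n = len(outcomes)
    return pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(n)],
            "signal": signal,
            "category": categories,
            "node_distance": node_distance if node_distance is not None else np.ones(n),
            "type": types if types is not None else ["true"] * n,
            "rec_pct": outcomes,
            "det_pct": outcomes,
        }
    )


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestCategoryModel:
    def test_constant_response(self):
        df = pair_frame(["separated"] * 5 + ["neighbours"] * 5, np.full(10, 4.2))
        table = fit_category_model(df, "rec", "posture")
        est = dict(zip(table.term, table.estimate))
        assert est["(intercept)"] == pytest.approx(4.2)
        assert est["neighbours"] == pytest.approx(0.0, abs=1e-12)

    def test_two_category_effect_is_mean_difference(self, rng):
        y_sep = rng.normal(3.0, 0.5, 12)
        y_nbr = rng.normal(4.5, 0.5, 12)
        df = pair_frame(
            ["separated"] * 12 + ["neighbours"] * 12, np.concatenate([y_sep, y_nbr])
        )
        table = fit_category_model(df, "rec", "posture")
        est = dict(zip(table.term, table.estimate))
        X = np.column_stack([np.ones(24), np.r_[np.zeros(12), np.ones(12)]])
        beta = ols_normal_equations(X, np.concatenate([y_sep, y_nbr]))
        assert est["(intercept)"] == pytest.approx(beta[0], abs=1e-8)
        assert est["neighbours"] == pytest.approx(beta[1], abs=1e-8)
        assert est["neighbours"] == pytest.approx(y_nbr.mean() - y_sep.mean(), abs=1e-8)

    def test_intercept_equals_reference_mean_on_balanced_data(self, rng):
        cats = ["separated", "neighbours", "distant"] * 8
        y = rng.normal(5, 1, 24)
        table = fit_category_model(pair_frame(cats, y), "rec", "posture")
        est = dict(zip(table.term, table.estimate))
        ref_mean = y[np.array(cats) == "separated"].mean()
        assert est["(intercept)"] == pytest.approx(ref_mean, abs=1e-8)

    def test_full_five_level_matches_normal_equations(self, rng):
        cats = list(
            itertools.chain.from_iterable(
                [[c] * 8 for c in ("separated", "neighbours", "distant",
                                   "imam_colocated", "imam_noncolocated")]
            )
        )
        y = rng.normal(3, 1, 40)
        table = fit_category_model(pair_frame(cats, y), "rec", "posture")
        est = dict(zip(table.term, table.estimate))
        dummies = ("distant", "imam_colocated", "imam_noncolocated", "neighbours")
        X = np.column_stack(
            [np.ones(40)] + [(np.array(cats) == c).astype(float) for c in dummies]
        )
        beta = ols_normal_equations(X, y)
        assert est["(intercept)"] == pytest.approx(beta[0], abs=1e-8)
        for i, c in enumerate(dummies, start=1):
            assert est[c] == pytest.approx(beta[i], abs=1e-8)


class TestSurrogateContrastModel:
    @staticmethod
    def simulate(rng, n_pairs=24, n_surr=3, tau=2.0, pair_sd=0.0, noise_sd=0.5):
        rows = []
        cats = ["separated", "neighbours"]
        for i in range(n_pairs):
            pair_effect = rng.normal(0, pair_sd)
            cat = cats[i % 2]
            base = 1.0 + (0.5 if cat == "neighbours" else 0.0) + pair_effect
            rows.append((f"p{i}", cat, "true", base + tau + rng.normal(0, noise_sd)))
            for _ in range(n_surr):
                rows.append((f"p{i}", cat, "surrogate", base + rng.normal(0, noise_sd)))
        df = pd.DataFrame(rows, columns=["pair_id", "category", "type", "rec_pct"])
        df["signal"] = "posture"
        df["det_pct"] = df["rec_pct"]
        df["node_distance"] = 1.0
        return df

    def test_zero_pair_variance_reduces_to_ols(self, rng):
        import statsmodels.formula.api as smf

        df = self.simulate(rng, pair_sd=0.0)
        table = fit_surrogate_contrast_model(df, "rec", "posture")
        data = df.rename(columns={"rec_pct": "y"})
        data["is_true"] = (data["type"] == "true").astype(float)
        ols = smf.ols(
            "y ~ C(category, Treatment(reference='separated')) * is_true", data=data
        ).fit()
        est = dict(zip(table.term, table.estimate))
        assert est["type"] == pytest.approx(ols.params["is_true"], abs=1e-6)
        assert est["(intercept)"] == pytest.approx(ols.params["Intercept"], abs=1e-6)

    def test_type_effect_recovery_across_replicates(self):
        """Known true-vs-surrogate shift recovered within 2 SE in >= 95% of fits."""
        tau = 2.0
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            df = self.simulate(r, n_pairs=20, n_surr=3, tau=tau, pair_sd=1.0)
            table = fit_surrogate_contrast_model(df, "rec", "posture")
            row = table[table.term == "type"].iloc[0]
            hits += abs(row.estimate - tau) <= 2 * row.std_error
        assert hits / n_rep >= 0.95


class TestNetworkModel:
    def test_exact_linear_relationship(self):
        nodes = np.array([1, 2, 3, 4] * 5, dtype=float)
        y = 6.0 - 0.5 * nodes
        df = pair_frame(["neighbours"] * 20, y, node_distance=nodes)
        table = fit_network_model(df, "rec", "posture")
        est = dict(zip(table.term, table.estimate))
        assert est["nodes"] == pytest.approx(-0.5, abs=1e-10)
        assert est["(intercept)"] == pytest.approx(6.0, abs=1e-10)

    def test_matches_normal_equations_on_noise(self, rng):
        nodes = rng.integers(1, 5, 30).astype(float)
        y = 4 - 0.3 * nodes + rng.normal(0, 0.4, 30)
        df = pair_frame(["distant"] * 30, y, node_distance=nodes)
        table = fit_network_model(df, "rec", "posture")
        beta = ols_normal_equations(np.column_stack([np.ones(30), nodes]), y)
        est = dict(zip(table.term, table.estimate))
        assert est["(intercept)"] == pytest.approx(beta[0], abs=1e-8)
        assert est["nodes"] == pytest.approx(beta[1], abs=1e-8)

    def test_infinite_distances_excluded(self, rng):
        nodes = np.array([1, 2, np.inf, 1, 2, np.inf] * 4, dtype=float)
        y = 5 - 0.5 * np.where(np.isfinite(nodes), nodes, 0)
        df = pair_frame(["distant"] * 24, y, node_distance=nodes)
        table = fit_network_model(df, "rec", "posture")
        est = dict(zip(table.term, table.estimate))
        assert est["nodes"] == pytest.approx(-0.5, abs=1e-10)

    def test_single_distance_value_rejected(self):
        df = pair_frame(["distant"] * 10, np.arange(10.0), node_distance=np.ones(10))
        with pytest.raises(ValueError):
            fit_network_model(df, "rec", "posture")


class TestLagTTest:
    def test_closed_form_small_sample(self):
        res = lag_t_test([1, 2, 3])
        assert res.mean == pytest.approx(2.0)
        assert res.df == 2
        assert res.t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-9)

    def test_zero_variance_flagged_degenerate(self):
        res = lag_t_test([0, 0, 0, 0])
        assert res.degenerate and res.mean == 0.0

    def test_symmetric_lags_give_zero_t(self):
        assert lag_t_test([-2, 2]).t == pytest.approx(0.0, abs=1e-12)

    @given(st.lists(st.integers(-5, 5), min_size=3, max_size=12))
    def test_antisymmetric_under_negation(self, lags):
        if len(set(lags)) < 2:
            return
        assert lag_t_test(lags).t == pytest.approx(-lag_t_test([-l for l in lags]).t)


class TestSpacing:
    def test_identical_samples(self):
        u, p = spacing_comparison([1.2, 1.3, 1.4], [1.2, 1.3, 1.4])
        assert u == pytest.approx(9 / 2)
        assert p > 0.5

    def test_complete_separation(self):
        u, _ = spacing_comparison([1, 2], [3, 4])
        assert u in (0.0, 4.0)

    @given(
        a=st.lists(st.floats(0.5, 3, allow_nan=False), min_size=2, max_size=8),
        b=st.lists(st.floats(0.5, 3, allow_nan=False), min_size=2, max_size=8),
    )
    def test_matches_exhaustive_counting(self, a, b):
        u, _ = spacing_comparison(a, b)
        brute = sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        )
        assert u == pytest.approx(brute)


class TestQuestionnaire:
    def test_reported_percentages(self):
        responses = pd.DataFrame(
            {
                "synchronized": ["yes"] * 24 + ["no"] * 3,
                "different": ["yes"] * 9 + ["no"] * 18,
                "coordinated": ["yes"] * 27,
            }
        )
        out = {q.question: q for q in summarize_questionnaire(responses)}
        assert out["synchronized"].pct_yes == 88.9
        assert out["different"].pct_yes == 33.3
        assert out["coordinated"].pct_yes == 100.0
        assert out["coordinated"].n_yes == 27

    def test_zero_yes(self):
        out = summarize_questionnaire(pd.DataFrame({"q": ["no"] * 5}))
        assert out[0].pct_yes == 0.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            summarize_questionnaire(pd.DataFrame({"q": ["yes", "maybe"]}))

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            summarize_questionnaire(pd.DataFrame({"q": ["yes", None]}))


class TestAuxiliaries:
    def test_stars_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == ""

    def test_holm_bounds_and_order(self, rng):
        p = rng.uniform(size=12)
        adj = holm_adjust(p)
        assert np.all((adj >= p - 1e-12) & (adj <= 1.0))
        assert np.all(adj[np.argsort(p)] == np.sort(adj))
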