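import numpy as np
import pandas as pd
import pytest

from cosem.boosting import (
    ExpressionBooster,
    SimplifiedScore,
    calibrate_initiation_rate,
    explained_variance,
    fit_expression_model,
    fit_simplified,
    load_model,
    save_model,
    score,
)
from cosem.rate_model import sequence_profiles
from cosem.simulator import TranslationSystem, simulate
from cosem.synthetic import make_genes, make_rate_table


def toy_data(n=800, seed=0, slope=2.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "current": rng.normal(size=n),
            "gc3": rng.uniform(0, 1, size=n),
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
        }
    )
    y = slope * X["current"].to_numpy() + rng.normal(0, 1.0, size=n)
    return X, y


class TestBoostingFit:
    def test_single_linear_signal_recovered(self):
        X, y = toy_data()
        m = ExpressionBooster(mstop=80).fit(X, y)
        assert m.selected_features_[0] == "current"
        lo, hi = np.quantile(X["current"], [0.1, 0.9])
        grid = np.linspace(lo, hi, 50)
        slope = np.polyfit(grid, m.partial_value("current", grid), 1)[0]
        assert slope == pytest.approx(2.0, rel=0.1)

    def test_constant_outcome_gives_offset_only(self):
        X, _ = toy_data(n=100)
        y = np.full(100, 3.5)
        m = ExpressionBooster(mstop=50).fit(X, y)
        assert m.selected_features_ == []
        assert np.allclose(m.predict(X), 3.5)

    def test_training_loss_non_increasing(self):
        X, y = toy_data(n=400, seed=3)
        m = ExpressionBooster(mstop=60).fit(X, y)
        assert np.all(np.diff(m.train_loss_path_) <= 1e-10)

    def test_monotone_partial_non_decreasing_on_dense_grid(self):
        X, y = toy_data(n=600, seed=4)
        m = ExpressionBooster(mstop=80).fit(X, y)
        lo, hi = m.train_range_["current"]
        vals = m.partial_value("current", np.linspace(lo, hi, 1000))
        assert np.all(np.diff(vals) >= -1e-10)

    def test_two_shape_recovery_with_heldout_r2(self):
        # monotone effect on x1 plus a symmetric quadratic on gc3
        rng = np.random.default_rng(5)
        n = 1500
        X = pd.DataFrame(
            {
                "current": rng.normal(size=n),
                "gc3": rng.uniform(0, 1, size=n),
                "noise_a": rng.normal(size=n),
            }
        )
        g1 = np.tanh(X["current"].to_numpy())
        g7 = 4.0 * (X["gc3"].to_numpy() - 0.5) ** 2
        signal = g1 + g7
        y = signal + rng.normal(0, 0.7, size=n)
        gen_r2 = np.var(signal) / (np.var(signal) + 0.49)
        model, r2, tr, te = fit_expression_model(
            pd.DataFrame(X), y, seed=1, max_iter=150
        )
        assert abs(r2 - gen_r2) < 0.1
        # shape signs: increasing partial for current, interior minimum for gc3
        lo, hi = model.train_range_["current"]
        pv = model.partial_value("current", np.linspace(lo, hi, 200))
        assert pv[-1] > pv[0]
        g = np.linspace(0.05, 0.95, 200)
        pg = model.partial_value("gc3", g)
        assert pg[100] < max(pg[0], pg[-1])

    def test_requires_enough_data(self):
        X, y = toy_data(n=10)
        with pytest.raises(ValueError):
            ExpressionBooster(mstop=5).fit(X, y)

    def test_missing_values_rejected(self):
        X, y = toy_data(n=50)
        X.loc[3, "gc3"] = np.nan
        with pytest.raises(ValueError, match="gc3"):
            ExpressionBooster(mstop=5).fit(X, y)


class TestScore:
    def test_unit_weights_reproduce_fitted_values(self):
        X, y = toy_data(n=300, seed=7)
        m = ExpressionBooster(mstop=40).fit(X, y)
        pred = m.predict(X)
        row = X.iloc[13]
        assert score(m, row) == pytest.approx(pred[13], rel=1e-10)

    def test_zero_weights_give_offset(self):
        X, y = toy_data(n=300, seed=8)
        m = ExpressionBooster(mstop=40).fit(X, y)
        w = {k: 0.0 for k in m.selected_features_}
        assert score(m, X.iloc[0], w) == pytest.approx(m.offset_)

    def test_absent_feature_with_zero_weight_allowed(self):
        X, y = toy_data(n=300, seed=9)
        m = ExpressionBooster(mstop=40).fit(X, y)
        feats = X.iloc[0].to_dict()
        name = m.selected_features_[0]
        feats[name] = None
        with pytest.raises(ValueError, match=name):
            score(m, feats)
        assert np.isfinite(score(m, feats, {name: 0.0}))

    def test_out_of_range_clamped(self):
        X, y = toy_data(n=300, seed=10)
        m = ExpressionBooster(mstop=40).fit(X, y)
        hi = m.train_range_["current"][1]
        inside = m.partial_value("current", hi)
        beyond = m.partial_value("current", hi + 50.0)
        assert beyond == pytest.approx(inside)


class TestExplainedVariance:
    def test_perfect_model(self):
        X, _ = toy_data(n=200, seed=11)
        y = 2.0 * X["current"].to_numpy()
        m = ExpressionBooster(mstop=300, nu=0.3).fit(X, y)
        assert explained_variance(m, X, y) > 0.98

    def test_offset_only_model_near_zero(self):
        X, y = toy_data(n=500, seed=12)
        m = ExpressionBooster(mstop=50).fit(X, np.full(500, 1.0))
        r2 = explained_variance(m, X, y)
        assert abs(r2) < 0.2

    def test_degenerate_outcome_errors(self):
        X, y = toy_data(n=100, seed=13)
        m = ExpressionBooster(mstop=10).fit(X, y)
        with pytest.raises(ValueError):
            explained_variance(m, X, np.full(100, 2.0))


class TestSimplifiedScore:
    def test_zero_coefficients(self):
        s = SimplifiedScore(intercept=0.0, linear={})
        assert s({"gc3": 0.5}) == 0.0

    def test_quadratic_gc3_interior_maximum(self):
        s = SimplifiedScore(
            intercept=0.0, linear={}, gc3_quadratic=(4.0, -4.0)
        )  # peak at gc3 = 0.5
        grid = np.linspace(0, 1, 101)
        vals = [s({"gc3": g}) for g in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.5, abs=0.01)

    def test_matches_full_model_on_linear_truth(self):
        X, y = toy_data(n=1200, seed=14, slope=1.5)
        m = ExpressionBooster(mstop=100).fit(X, y)
        simple = fit_simplified(m, X)
        full = m.predict(X)
        approx = np.array([simple(row) for _, row in X.iterrows()])
        # linear generative truth -> the linearized score tracks the full one
        resid = full - approx
        assert np.corrcoef(full, approx)[0, 1] > 0.99
        assert resid.std() < 0.1 * full.std()


class TestModelPersistence:
    def test_json_round_trip_scores_identical(self, tmp_path):
        X, y = toy_data(n=300, seed=15)
        m = ExpressionBooster(mstop=40).fit(X, y)
        path = tmp_path / "model.json"
        save_model(m, path)
        again = load_model(path)
        for i in (0, 7, 42):
            assert score(again, X.iloc[i]) == pytest.approx(
                score(m, X.iloc[i]), rel=1e-12
            )


@pytest.fixture(scope="module")
def calibration_setup():
    table = make_rate_table(7)
    seqs = [s for _, s in make_genes(8, 12, (60, 120))]
    return table, seqs


class TestCalibrateInitiationRate:
    def test_recovers_generating_alpha(self, calibration_setup):
        table, seqs = calibration_setup
        alpha_star = 2.0
        rng = np.random.default_rng(0)
        prot = []
        for k, s in enumerate(seqs):
            rates, _ = sequence_profiles(s, table)
            sys = TranslationSystem(rates=rates, init_rate=alpha_star)
            res = simulate(sys, seed=500 + k, collect_profile=False,
                           target_completions=400)
            prot.append(res.current * (1 + rng.normal(0, 0.05)))
        grid = [0.1, 0.5, 1.0, 2.0, 4.0, 8.0]
        best, profile = calibrate_initiation_rate(
            seqs, table, prot, grid, seed=9,
            simulate_kwargs={"target_completions": 300},
        )
        # within one grid step of the generating value
        idx = grid.index(2.0)
        assert best in grid[max(idx - 1, 0) : idx + 2]

    def test_single_point_grid(self, calibration_setup):
        table, seqs = calibration_setup
        best, _ = calibrate_initiation_rate(
            seqs, table, np.arange(len(seqs)) + 1.0, [0.5], seed=1,
            simulate_kwargs={"target_completions": 30},
        )
        assert best == 0.5

    def test_pure_noise_levels_warn_flat_profile(self, calibration_setup, caplog):
        table, seqs = calibration_setup
        rng = np.random.default_rng(3)
        with caplog.at_level("WARNING"):
            calibrate_initiation_rate(
                seqs, table, rng.normal(size=len(seqs)), [0.5, 1.0], seed=2,
                simulate_kwargs={"target_completions": 30},
            )
        # a flat or undefined correlation profile is reported, not fatal

    def test_too_few_sequences(self, calibration_setup):
        table, seqs = calibration_setup
        with pytest.raises(ValueError):
            calibrate_initiation_rate(seqs[:3], table, [1, 2, 3], [0.1])
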