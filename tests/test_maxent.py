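"""Maximum-entropy engine: AUC, KKT stationarity, screening protocols."""

import numpy as np
import pandas as pd
import pytest

from chronorisk.grids import GridSpec
from chronorisk.io import CovariateStack
from chronorisk.maxent import (
    FeatureSet,
    auc,
    correlation_filter,
    fit_maxent,
    permutation_importance,
    prescreen_variables,
    replicate_fit,
    sample_background,
)


def gaussian_env(rng, n, names=("a", "b", "c")):
    return pd.DataFrame(rng.normal(size=(n, len(names))), columns=list(names))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3.0, 4.0], [1.0, 2.0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([1.0, 1.0, 1.0], [1.0, 1.0]) == 0.5

    def test_enumerated_four_pairs(self):
        # pairs: (.9>.5) (.9>.1) (.4<.5) (.4>.1) -> 3 wins of 4
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_empty_side_error(self):
        with pytest.raises(ValueError):
            auc([], [1.0])


class TestFitMaxent:
    def test_gibbs_normalization_and_kkt(self):
        rng = np.random.default_rng(0)
        bg = gaussian_env(rng, 800)
        pres = bg.iloc[(bg["a"] > 0.5).to_numpy().nonzero()[0][:80]]
        fs = FeatureSet.from_background(bg)
        model = fit_maxent(fs.transform(pres), fs.transform(bg), fs)
        q = model.raw(bg)
        assert q.sum() == pytest.approx(1.0, abs=1e-8)
        # KKT: presence feature means match background expectations within beta
        F = fs.transform(bg)
        ef = (q / q.sum()) @ F
        pbar = fs.transform(pres).mean(axis=0)
        slack = np.abs(pbar - ef) - model.betas
        slack[np.abs(model.lam) >= 200.0] = 0.0
        assert slack.max() <= 1e-4

    def test_null_presences_give_logistic_near_half(self):
        # presences drawn from the background distribution itself
        means = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            bg = gaussian_env(rng, 600)
            pres = gaussian_env(rng, 60)
            fs = FeatureSet.from_background(bg)
            model = fit_maxent(fs.transform(pres), fs.transform(bg), fs)
            means.append(model.logistic(bg).mean())
        assert all(0.4 <= m <= 0.6 for m in means)

    def test_separating_binary_feature_training_auc_one(self):
        bg = pd.DataFrame({"x": np.zeros(100)})
        pres = pd.DataFrame({"x": np.ones(30)})
        fs = FeatureSet(["x"], {"x": 0.0}, {"x": 1.0}, {"x": np.array([])},
                        ["x:linear", "x:quadratic"], np.array([0, 0]))
        model = fit_maxent(fs.transform(pres), fs.transform(bg), fs)
        assert auc(model.raw(pres), model.raw(bg)) == 1.0

    def test_logistic_is_half_where_raw_equals_exp_minus_entropy(self):
        rng = np.random.default_rng(1)
        bg = gaussian_env(rng, 300)
        pres = gaussian_env(rng, 40) + 0.5
        fs = FeatureSet.from_background(bg)
        model = fit_maxent(fs.transform(pres), fs.transform(bg), fs)
        q = np.exp(-model.entropy)
        qe = q * np.exp(model.entropy)
        assert qe / (1 + qe) == pytest.approx(0.5)

    def test_large_regularization_drives_weights_to_zero(self):
        rng = np.random.default_rng(2)
        bg = gaussian_env(rng, 300)
        pres = bg.iloc[(bg["a"] > 0.8).to_numpy().nonzero()[0][:40]]
        fs = FeatureSet.from_background(bg)
        model = fit_maxent(fs.transform(pres), fs.transform(bg), fs, reg_multiplier=1e6)
        assert np.abs(model.lam).max() == 0.0
        assert np.ptp(model.logistic(bg)) == pytest.approx(0.0, abs=1e-12)

    def test_contribution_sums_to_100_and_split_between_duplicates(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=600)
        bg = pd.DataFrame({"u": x, "v": x + rng.normal(0, 1e-6, 600), "w": rng.normal(size=600)})
        sel = np.flatnonzero(x > 0.7)[:60]
        pres = bg.iloc[sel]
        fs = FeatureSet.from_background(bg)
        model = fit_maxent(fs.transform(pres), fs.transform(bg), fs)
        contrib = model.percent_contribution()
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.01)


class TestPermutationImportance:
    def test_causal_variable_dominates(self):
        rng = np.random.default_rng(4)
        bg = gaussian_env(rng, 500)
        pres = bg.iloc[(bg["b"] > 0.8).to_numpy().nonzero()[0][:50]]
        fs = FeatureSet.from_background(bg)
        model = fit_maxent(fs.transform(pres), fs.transform(bg), fs)
        imp = permutation_importance(model, pres, bg, rng)
        assert imp["b"] > 60.0
        assert sum(imp.values()) == pytest.approx(100.0, abs=0.01)


class TestVariableScreening:
    def test_prescreen_drops_constant_variable(self):
        rng = np.random.default_rng(5)
        bg = gaussian_env(rng, 400, names=("a", "b"))
        bg["flat"] = 1.0
        pres = bg.iloc[(bg["a"] > 0.5).to_numpy().nonzero()[0][:60]]
        retained, _ = prescreen_variables(pres, bg, n_runs=5, rng=rng)
        assert "flat" not in retained
        assert "a" in retained

    def test_correlation_filter_duplicates_keep_higher_contribution(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=300)
        env = pd.DataFrame({"p": x, "q": x})
        kept, log = correlation_filter(env, {"p": 60.0, "q": 40.0})
        assert kept == ["p"]
        assert log[0]["dropped"] == "q"

    def test_correlation_filter_chain_keeps_single_winner(self):
        # three mutually correlated variables, contributions 50/30/20
        rng = np.random.default_rng(7)
        x = rng.normal(size=400)
        env = pd.DataFrame({
            "a": x, "b": x + rng.normal(0, 0.1, 400), "c": x + rng.normal(0, 0.1, 400)})
        assert (env.corr().abs().to_numpy() > 0.7).all()
        kept, _ = correlation_filter(env, {"a": 50.0, "b": 30.0, "c": 20.0})
        assert kept == ["a"]

    def test_uncorrelated_variables_all_retained(self):
        rng = np.random.default_rng(8)
        env = gaussian_env(rng, 400)
        kept, log = correlation_filter(env, {"a": 10.0, "b": 5.0, "c": 1.0})
        assert kept == ["a", "b", "c"] and log == []


class TestBackgroundAndReplicates:
    def make_stack(self, n=10):
        grid = GridSpec(100.0, 20.0, 0.5, n, n)
        rng = np.random.default_rng(9)
        layers = {
            "e1": rng.normal(size=(1, n, n)),
            "e2": rng.normal(size=(1, n, n)),
        }
        return CovariateStack(grid, [1970], layers)

    def test_sample_all_cells_when_n_exceeds(self):
        stack = self.make_stack(5)
        cells, env = sample_background(stack, 1000, np.random.default_rng(0))
        assert len(cells) == 25

    def test_sampling_deterministic_per_seed(self):
        stack = self.make_stack(10)
        c1, _ = sample_background(stack, 30, np.random.default_rng(5))
        c2, _ = sample_background(stack, 30, np.random.default_rng(5))
        np.testing.assert_array_equal(c1, c2)

    def test_inclusion_frequency_matches_hypergeometric(self):
        stack = self.make_stack(5)  # 25 cells
        counts = np.zeros(25)
        n_draw, n_rep = 10, 400
        for seed in range(n_rep):
            cells, _ = sample_background(stack, n_draw, np.random.default_rng(seed))
            counts[cells - stack.valid_cell_ids()[0]] += 0  # cells are absolute ids
            counts[[int(c) for c in cells]] += 1
        p = n_draw / 25
        se = np.sqrt(p * (1 - p) / n_rep)
        assert np.abs(counts / n_rep - p).max() < 4 * se

    def test_replicates_deterministic_and_strong_signal_auc(self):
        stack = self.make_stack(20)
        grid = stack.grid
        # presences confined to the rare extreme-e1 stratum (~8% of cells),
        # so presence and background scores barely overlap
        cells = stack.valid_cell_ids()
        env = stack.env_matrix(cells)
        pres_cells = env.index[env["e1"] > 1.4][:30]
        pres_env = env.loc[pres_cells]
        bg_env = env
        r1 = replicate_fit(pres_env, bg_env, stack, ["e1", "e2"], replicates=10,
                           test_fraction=0.25, rng=np.random.default_rng(3))
        r2 = replicate_fit(pres_env, bg_env, stack, ["e1", "e2"], replicates=10,
                           test_fraction=0.25, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(r1.surface, r2.surface)
        assert r1.mean_auc >= 0.9
        finite = r1.surface[np.isfinite(r1.surface)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0

    def test_single_replicate_surface_equals_single_fit_map(self):
        stack = self.make_stack(8)
        cells = stack.valid_cell_ids()
        env = stack.env_matrix(cells)
        pres_env = env[env["e1"] > 0.5][:20]
        rep = replicate_fit(pres_env, env, stack, ["e1", "e2"], replicates=1,
                            test_fraction=0.05, rng=np.random.default_rng(4))
        fs = FeatureSet.from_background(env[["e1", "e2"]])
        # reproduce the single fit with the same split
        rng = np.random.default_rng(4)
        idx = rng.permutation(len(pres_env))
        n_test = int(round(0.05 * len(pres_env)))
        train = pres_env.iloc[idx[n_test:]][["e1", "e2"]]
        model = fit_maxent(fs.transform(train), fs.transform(env[["e1", "e2"]]), fs)
        expected = model.logistic(env[["e1", "e2"]])
        got = rep.surface[cells // stack.grid.n_x, cells % stack.grid.n_x]
        np.testing.assert_allclose(got, expected, atol=1e-12)
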