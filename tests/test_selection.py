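import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from oakselect.selection import (analyze_selection, linear_gradients,
                                 quadratic_gradients, relative_fitness,
                                 response_to_selection,
                                 selection_differentials, standardize,
                                 vif_screen)

TRAITS = ["RGR", "WBI", "CCI", "ANT"]


def _sel_frame(rng, n=600, beta=0.08, noise=0.3):
    Z = rng.normal(size=(n, 4))
    w = 1.0 + beta * Z[:, 0] + rng.normal(0, noise, n)
    df = pd.DataFrame(Z, columns=TRAITS)
    df["w"] = w
    return df


class TestRelativeFitness:
    def test_equal_fitness_gives_unit_w(self):
        w = relative_fitness(np.full(5, 7.0))
        np.testing.assert_allclose(w, 1.0)

    def test_worked_values(self):
        w = relative_fitness(np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(w, [0.5, 1.0, 1.5])

    def test_within_group_mean_one(self, rng):
        f = rng.uniform(1, 50, 90)
        g = rng.integers(0, 3, 90)
        w = relative_fitness(f, g)
        for k in range(3):
            assert abs(w[g == k].mean() - 1.0) < 1e-12

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            relative_fitness(np.array([0.0, 0.0]))


class TestStandardize:
    def test_mean_zero_sd_one(self, rng):
        df = pd.DataFrame({"t": rng.uniform(0, 5, 40),
                           "g": rng.integers(0, 2, 40)})
        out = standardize(df, ["t"], "g")
        for _, sub in out.groupby("g"):
            assert abs(sub["t"].mean()) < 1e-12
            assert abs(sub["t"].std(ddof=1) - 1.0) < 1e-12

    def test_idempotent(self, rng):
        df = pd.DataFrame({"t": rng.normal(size=30)})
        once = standardize(df, ["t"])
        twice = standardize(once, ["t"])
        np.testing.assert_allclose(twice["t"], once["t"], atol=1e-12)

    def test_three_point_example(self):
        out = standardize(pd.DataFrame({"t": [1.0, 2.0, 3.0]}), ["t"])
        np.testing.assert_allclose(out["t"], [-1.0, 0.0, 1.0])

    def test_constant_trait_named_in_error(self):
        with pytest.raises(ValueError, match="'t'"):
            standardize(pd.DataFrame({"t": [2.0, 2.0, 2.0]}), ["t"])


class TestVIF:
    def test_orthogonal_columns_all_retained(self):
        n = 32
        base = np.eye(n)[:, :3] - 1.0 / n
        df = pd.DataFrame(base, columns=["a", "b", "c"])
        retained, report = vif_screen(df, ["a", "b", "c"])
        assert retained == ["a", "b", "c"]
        first = report[report["round"] == 1]
        assert np.allclose(first["vif"], 1.0, atol=0.2)

    def test_duplicate_column_dropped(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        df["dup"] = df["a"]
        retained, report = vif_screen(df, ["a", "b", "c", "dup"])
        assert len(retained) == 3
        assert ("a" in retained) != ("dup" in retained)  # one copy survives
        assert np.isinf(report[report["round"] == 1]["vif"]).sum() == 2

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(80, 3))
        X[:, 2] += 0.8 * X[:, 0]
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        _, report = vif_screen(df, ["a", "b", "c"], threshold=1e9)
        for name, j in [("a", 0), ("b", 1), ("c", 2)]:
            others = [k for k in range(3) if k != j]
            r2 = sm.OLS(X[:, j], sm.add_constant(X[:, others])).fit().rsquared
            got = report.set_index("trait").loc[name, "vif"]
            assert abs(got - 1.0 / (1.0 - r2)) < 1e-10


class TestLinearGradients:
    def test_equals_ols_without_random_effects(self, rng):
        df = _sel_frame(rng)
        out = linear_gradients(df, TRAITS)
        ols = sm.OLS(df["w"], sm.add_constant(df[TRAITS])).fit()
        np.testing.assert_allclose(out["estimate"], ols.params[TRAITS],
                                   atol=1e-6)
        np.testing.assert_allclose(out["p"], [ols.pvalues[t] for t in TRAITS],
                                   atol=1e-9)

    def test_recovers_generating_gradient(self, rng):
        df = _sel_frame(rng, n=600, beta=0.08)
        out = linear_gradients(df, TRAITS).set_index("trait")
        est, se = out.loc["RGR", "estimate"], out.loc["RGR", "se"]
        assert abs(est - 0.08) < 3 * se
        assert 0.05 <= est <= 0.11

    def test_lande_arnold_identity(self, rng):
        # beta = P^-1 S for OLS on standardized traits
        df = _sel_frame(rng, n=400)
        df[TRAITS] = standardize(df, TRAITS)[TRAITS]
        beta = linear_gradients(df, TRAITS)["estimate"].to_numpy()
        S = selection_differentials(df, TRAITS)["estimate"].to_numpy()
        P = np.cov(df[TRAITS].to_numpy().T, ddof=1)
        np.testing.assert_allclose(beta, np.linalg.solve(P, S), atol=1e-8)

    def test_row_permutation_invariant(self, rng):
        df = _sel_frame(rng, n=200)
        a = linear_gradients(df, TRAITS)["estimate"].to_numpy()
        b = linear_gradients(df.sample(frac=1.0, random_state=1),
                             TRAITS)["estimate"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_mixed_model_close_to_ols_with_block_variance(self, rng):
        df = _sel_frame(rng, n=600)
        block = np.repeat(np.arange(6), 100)
        df["w"] = df["w"] + rng.normal(0, 0.15, 6)[block]
        df["block"] = block.astype(str)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = linear_gradients(df, TRAITS, random_groups=["block"])
        assert out.attrs["random_effects_used"]
        ols = sm.OLS(df["w"], sm.add_constant(df[TRAITS])).fit()
        np.testing.assert_allclose(out["estimate"], ols.params[TRAITS],
                                   atol=0.02)


class TestDifferentials:
    def test_constant_fitness_zero(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=TRAITS)
        df["w"] = 1.0
        out = selection_differentials(df, TRAITS)
        np.testing.assert_allclose(out["estimate"], 0.0, atol=1e-15)

    def test_hand_covariance_oracle(self):
        # sample covariance of w={0.5,1.5,0.8,1.2} with z: deviations
        # (-.5,.5,-.2,.2) x (-1.161,1.161,-.387,.387) sum 1.3158, /3
        df = pd.DataFrame({"z": [-1.161, 1.161, -0.387, 0.387],
                           "w": [0.5, 1.5, 0.8, 1.2]})
        out = selection_differentials(df, ["z"])
        assert abs(out["estimate"].iloc[0] - 1.3158 / 3.0) < 1e-10

    def test_equals_beta_for_uncorrelated_traits(self):
        # orthogonal design columns: beta_j = S_j / var(z_j) and var = 1
        rng = np.random.default_rng(8)
        n = 500
        Z = rng.normal(size=(n, 4))
        Q, _ = np.linalg.qr(Z - Z.mean(axis=0))
        Z = Q * np.sqrt(n - 1)  # exactly orthonormal, sd 1
        df = pd.DataFrame(Z, columns=TRAITS)
        df["w"] = 1 + 0.1 * Z[:, 0] + 0.05 * Z[:, 2]
        beta = linear_gradients(df, TRAITS)["estimate"].to_numpy()
        S = selection_differentials(df, TRAITS)["estimate"].to_numpy()
        np.testing.assert_allclose(beta, S, atol=1e-10)


class TestQuadratic:
    def test_recovers_stabilizing_surface(self, rng):
        df = _sel_frame(rng, beta=0.0)
        df["w"] = 1.2 - 0.05 * df["RGR"] ** 2 + rng.normal(0, 0.3, len(df))
        out = quadratic_gradients(df, TRAITS).set_index("trait")
        assert -0.08 <= out.loc["RGR", "estimate"] <= -0.02
        assert out.loc["RGR", "selection_mode"] == "stabilizing"

    def test_linear_surface_gamma_near_zero(self, rng):
        est = []
        for seed in range(30):
            df = _sel_frame(np.random.default_rng(seed), n=300, beta=0.1)
            out = quadratic_gradients(df, ["RGR"])
            est.append(out["estimate"].iloc[0])
        assert abs(np.mean(est)) < 0.01

    def test_sign_labels(self, rng):
        df = _sel_frame(rng, n=100)
        out = quadratic_gradients(df, TRAITS)
        lab = np.where(out["estimate"] < 0, "stabilizing", "disruptive")
        assert (out["selection_mode"] == lab).all()


class TestResponse:
    def test_breeders_equation_values(self):
        assert response_to_selection(0.5, 0.2) == 0.1
        assert response_to_selection(0.0, 5.0) == 0.0

    def test_sign_matches_differential(self, rng):
        h2 = rng.uniform(0.01, 1.0, 20)
        s = rng.normal(size=20)
        r = response_to_selection(h2, s)
        assert np.all(np.sign(r) == np.sign(s))

    def test_invalid_h2(self):
        with pytest.raises(ValueError):
            response_to_selection(1.2, 0.1)


class TestAnalyzeSelection:
    def test_single_population_levels_coincide(self, rng):
        n = 300
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=TRAITS)
        df["garden"] = "MN"
        df["population"] = "P1"
        df["block"] = (np.arange(n) % 5).astype(str)
        df["fitness_hat"] = 50 + 4 * df["RGR"] + rng.normal(0, 5, n)
        garden = analyze_selection(df, TRAITS, level="garden")
        pop = analyze_selection(df, TRAITS, level="population")
        for param in ("beta", "S", "gamma"):
            a = garden[garden["parameter"] == param].set_index("trait")["estimate"]
            b = pop[pop["parameter"] == param].set_index("trait")["estimate"]
            np.testing.assert_allclose(a, b[a.index], atol=1e-6)

    def test_full_table_shape(self, small_bundle, rng):
        table = small_bundle.table.copy()
        table["fitness_hat"] = table["fitness_obs"] + 1e-3  # keep means positive
        out = analyze_selection(table, ["RGR", "WBI", "CCI"], level="garden")
        retained = out.attrs["retained_traits"]
        assert set(out["parameter"]) == {"beta", "S", "gamma"}
        assert len(out) == 3 * len(retained) * 3  # gardens x params x traits
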