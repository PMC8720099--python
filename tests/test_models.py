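import numpy as np
import pytest

from conftest import orthogonal_predictors
from geobiodiv.models import (collinearity_screen, filter_soil_models,
                              select_by_aic, stepwise_linear,
                              variance_partition, LinearFitSummary)


def mix_to_target_r(base, rng, r):
    """Construct a vector with exact sample correlation r to base."""
    noise = rng.standard_normal(base.size)
    b = (base - base.mean()) / base.std()
    e = noise - noise.mean()
    e -= b * (e @ b) / (b @ b)   # orthogonalize
    e /= e.std()
    return r * b + np.sqrt(1 - r ** 2) * e


class TestCollinearityScreen:
    def test_duplicate_flagged_with_r_one(self, rng):
        x = rng.uniform(0, 1, 50)
        rep = collinearity_screen({"a": x, "b": x.copy()})
        assert len(rep.pairs) == 1
        assert rep.pairs[0][2] == pytest.approx(1.0)

    def test_orthogonal_vectors_pass(self, rng):
        a, b, c = orthogonal_predictors(60, seed=3)
        rep = collinearity_screen({"a": a, "b": b, "c": c})
        assert not rep

    @pytest.mark.parametrize("r, flagged", [(0.59, False), (0.61, True)])
    def test_threshold_semantics(self, rng, r, flagged):
        base = rng.standard_normal(400)
        other = mix_to_target_r(base, rng, r)
        rep = collinearity_screen({"a": base, "b": other})
        assert bool(rep.pairs) == flagged

    def test_zero_variance_reported_not_paired(self, rng):
        x = rng.uniform(0, 1, 30)
        rep = collinearity_screen({"a": x, "flat": np.full(30, 2.0)})
        assert rep.zero_variance == ("flat",)
        assert not rep.pairs


class TestSelectByAic:
    def test_driver_beats_noise(self):
        wins = 0
        reps = 60
        for s in range(reps):
            r = np.random.default_rng(s)
            driver = r.uniform(0, 1, 80)
            noise = r.uniform(0, 1, 80)
            y = 2 * driver + 0.3 * r.standard_normal(80)
            if select_by_aic(y, {"driver": driver, "noise": noise}) == "driver":
                wins += 1
        assert wins / reps >= 0.95

    def test_single_variant_returned(self, rng):
        x = rng.uniform(0, 1, 40)
        assert select_by_aic(x + 0.1, {"only": x}) == "only"

    def test_identical_variants_tie_by_name(self, rng):
        x = rng.uniform(0, 1, 40)
        y = x + 0.05 * rng.standard_normal(40)
        assert select_by_aic(y, {"zeta": x, "alpha": x.copy()}) == "alpha"


class TestVariancePartition:
    def test_components_sum_to_full_deviance(self, rng):
        a, b, c = orthogonal_predictors(200, seed=11)
        y = a + 0.5 * b - c + 0.4 * rng.standard_normal(200)
        vp = variance_partition(y, a, b, c)
        assert vp.total() == pytest.approx(vp.full_deviance, abs=1e-10)

    def test_duplicated_predictor_zero_pure(self, rng):
        a = rng.uniform(0, 1, 150)
        c = rng.uniform(0, 1, 150)
        y = a + c + 0.2 * rng.standard_normal(150)
        vp = variance_partition(y, a, a.copy(), c)
        assert abs(vp.pure["a"]) < 1e-6
        assert abs(vp.pure["b"]) < 1e-6

    def test_orthogonal_design_negligible_shared(self, rng):
        a, b, c = orthogonal_predictors(1000, seed=7)
        y = a + b + c + 0.5 * rng.standard_normal(1000)
        vp = variance_partition(y, a, b, c)
        for v in vp.pairwise_shared.values():
            assert abs(v) < 0.02
        assert abs(vp.triple_shared) < 0.02

    def test_matches_linear_r2_algebra(self, rng):
        """Oracle: for linear signal, frozen-smoothing deviances collapse to
        nested OLS R^2, so components match closed-form R^2 algebra."""
        n = 800
        a, b, c = orthogonal_predictors(n, seed=23)
        # correlated pair via mixing
        b = 0.6 * a + 0.8 * b
        y = a + b + 0.3 * c + 0.5 * rng.standard_normal(n)
        vp = variance_partition(y, a, b, c)

        def ols_r2(*cols):
            X = np.column_stack([np.ones(n), *cols])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = np.sum((y - X @ beta) ** 2)
            return 1 - rss / np.sum((y - y.mean()) ** 2)

        D = {"abc": ols_r2(a, b, c), "ab": ols_r2(a, b), "ac": ols_r2(a, c),
             "bc": ols_r2(b, c), "a": ols_r2(a), "b": ols_r2(b), "c": ols_r2(c)}
        assert vp.pure["a"] == pytest.approx(D["abc"] - D["bc"], abs=0.01)
        assert vp.pure["b"] == pytest.approx(D["abc"] - D["ac"], abs=0.01)
        assert vp.pure["c"] == pytest.approx(D["abc"] - D["ab"], abs=0.01)
        d_lin = D["ac"] + D["bc"] - D["c"] - D["abc"]
        assert vp.pairwise_shared["d"] == pytest.approx(d_lin, abs=0.01)

    def test_nesting_monotonicity_on_fixtures(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            a, b, c = orthogonal_predictors(300, seed=seed + 100)
            y = a + np.sin(2 * b) + 0.4 * r.standard_normal(300)
            vp = variance_partition(y, a, b, c)
            D = vp.subset_deviance
            na, nb, nc = "climate", "habitat", "soil"
            assert D[na] <= D[f"{na}+{nb}"] + 1e-8
            assert D[nb] <= D[f"{nb}+{nc}"] + 1e-8
            assert D[f"{na}+{nb}"] <= D[f"{na}+{nb}+{nc}"] + 1e-8


class TestStepwise:
    def test_true_predictor_found(self):
        hits = 0
        reps = 60
        for s in range(reps):
            r = np.random.default_rng(s)
            X = {f"n{i}": r.standard_normal(100) for i in range(4)}
            X["signal"] = r.standard_normal(100)
            y = 3 * X["signal"] + 0.5 * r.standard_normal(100)
            fit = stepwise_linear(y, X)
            if "signal" in fit.terms:
                hits += 1
        assert hits / reps >= 0.95

    def test_pure_noise_nearly_empty(self):
        sizes, r2s = [], []
        for s in range(40):
            r = np.random.default_rng(1000 + s)
            X = {f"n{i}": r.standard_normal(100) for i in range(4)}
            y = r.standard_normal(100)
            fit = stepwise_linear(y, X)
            sizes.append(len(fit.terms))
            r2s.append(fit.adj_r2)
        assert np.mean(sizes) < 1.0
        assert np.mean(r2s) < 0.05

    def test_exact_linear_single_term(self, rng):
        x = rng.standard_normal(50)
        noise_col = rng.standard_normal(50)
        fit = stepwise_linear(2 * x + 1, {"x": x, "z": noise_col})
        assert fit.terms == ("x",)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)


class TestSoilFilter:
    def make(self, adj):
        return LinearFitSummary(name=f"m{adj}", terms=(), coefficients={},
                                r2=adj, adj_r2=adj, aic=0.0, n=50)

    def test_threshold_is_strict(self):
        fits = [self.make(0.44), self.make(0.46)]
        kept = filter_soil_models(fits)
        assert [f.adj_r2 for f in kept] == [0.46]

    def test_empty_and_all_above(self):
        assert filter_soil_models([]) == []
        fits = [self.make(0.5), self.make(0.69)]
        assert len(filter_soil_models(fits)) == 2
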