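import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from rhythmeg.stats import (BetaRegression, beta_regression_fit, bh_fdr,
                            boundary_adjust, cluster_bootstrap,
                            minmax_normalize, ortho_poly, slope_contrast)
from rhythmeg.synthetic import BehaviorGenSpec, gen_behavior


class TestBoundaryAdjust:
    def test_stated_rule(self):
        out = boundary_adjust([0.0, 0.5, 1.0])
        assert np.allclose(out, [1 / 6, 0.5, 5 / 6])

    def test_interior_values_untouched(self):
        y = np.array([0.2, 0.5, 0.9])
        assert np.array_equal(boundary_adjust(y), y)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            boundary_adjust([0.0, 0.0, 0.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            boundary_adjust([-0.1, 0.5])

    def test_per_group_mode(self):
        y = [0.0, 0.4, 0.0, 0.8]
        out = boundary_adjust(y, groups=[0, 0, 1, 1])
        assert out[0] == pytest.approx(0.2 / 2)
        assert out[2] == pytest.approx(0.4 / 2)


class TestMinmax:
    def test_examples(self):
        assert np.allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])
        y = np.array([0.0, 0.3, 1.0])
        assert np.allclose(minmax_normalize(y), y)

    def test_order_preserved(self, rng):
        x = rng.standard_normal(100)
        assert np.array_equal(np.argsort(minmax_normalize(x)), np.argsort(x))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([1.0, 1.0])


class TestOrthoPoly:
    def test_orthonormal_zero_mean(self, rng):
        x = rng.standard_normal(200)
        basis = ortho_poly(x, 3)
        assert np.allclose(basis.T @ basis, np.eye(3), atol=1e-10)
        assert np.allclose(basis.mean(axis=0), 0.0, atol=1e-12)

    def test_degree_one_is_proportional_to_centred_x(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        basis = ortho_poly(x, 1)
        corr = np.corrcoef(basis[:, 0], x)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_sign(self, rng):
        x = rng.standard_normal(100)
        a = ortho_poly(x, 2)
        b = ortho_poly(x, 2)
        assert np.array_equal(a, b)
        # linear column correlates positively with x
        assert np.corrcoef(a[:, 0], x)[0, 1] > 0

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            ortho_poly([1.0, 1.0, 2.0], 2)


class TestBetaRegression:
    def test_intercept_only_matches_sample_mean(self, rng):
        y = rng.beta(4, 2, size=2000)
        est = BetaRegression().fit(pd.DataFrame(index=range(len(y))), y)
        assert expit(est.params_["intercept"]) == pytest.approx(y.mean(),
                                                                abs=1e-3)

    def test_known_coefficients_recovered(self, rng):
        n = 2000
        design = pd.DataFrame({"x": rng.standard_normal(n)})
        data = gen_behavior(design, BehaviorGenSpec(
            fixed_coefficients={"intercept": 0.3, "x": 0.8},
            precision=30.0, seed=5))
        fit = beta_regression_fit(design, data["score"])
        assert fit.params["x"] == pytest.approx(0.8, abs=3 * fit.bse["x"])
        assert fit.phi == pytest.approx(30.0, rel=0.15)
        assert fit.converged
        assert 0 < fit.pseudo_r2 <= 1

    def test_non_interior_response_directed_to_boundary_adjust(self):
        design = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="boundary_adjust"):
            BetaRegression().fit(design, np.array([0.0, 0.5, 0.9]))

    def test_rank_deficiency_names_collinear_column(self, rng):
        x = rng.standard_normal(100)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            BetaRegression().fit(design, np.full(100, 0.5))

    def test_predict_matches_link_inverse(self, rng):
        design = pd.DataFrame({"x": rng.standard_normal(500)})
        data = gen_behavior(design, BehaviorGenSpec(
            fixed_coefficients={"intercept": 0.2, "x": 0.5}, seed=6))
        est = BetaRegression().fit(design, data["score"])
        manual = expit(est.intercept_ + est.coef_[0] * design["x"])
        assert np.allclose(est.predict(design), manual)

    def test_sklearn_param_interface(self):
        est = BetaRegression(add_intercept=False)
        assert est.get_params()["add_intercept"] is False
        est.set_params(maxiter=100)
        assert est.maxiter == 100


class TestClusterBootstrap:
    def test_independent_rows_match_model_se(self, rng):
        n = 400
        design = pd.DataFrame({"x": rng.standard_normal(n)})
        data = gen_behavior(design, BehaviorGenSpec(
            fixed_coefficients={"intercept": 0.2, "x": 0.5},
            precision=20.0, seed=7))
        fit = beta_regression_fit(design, data["score"])
        boot = cluster_bootstrap(design, data["score"], np.arange(n),
                                 B=200, seed=1)
        assert boot.loc["x", "boot_se"] == pytest.approx(
            fit.bse["x"], rel=0.15)

    def test_cluster_heterogeneity_inflates_se(self, rng):
        n_sub, per = 20, 30
        design = pd.DataFrame({
            "x": rng.standard_normal(n_sub * per),
            "subject": np.repeat(np.arange(n_sub), per),
        })
        data = gen_behavior(design, BehaviorGenSpec(
            fixed_coefficients={"intercept": 0.2, "x": 0.3},
            precision=20.0, subject_sd=1.0, seed=8))
        fit = beta_regression_fit(design[["x"]], data["score"])
        boot = cluster_bootstrap(design[["x"]], data["score"],
                                 design["subject"], B=200, seed=2)
        assert boot.loc["intercept", "boot_se"] > 1.5 * fit.bse["intercept"]

    def test_too_few_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_bootstrap(pd.DataFrame({"x": [0.1] * 20}),
                              np.full(20, 0.5), np.repeat([0, 1], 10), B=200)


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_hand_computed_stepup(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_brute_force_on_small_sets(self, rng):
        grid = [0.001, 0.01, 0.02, 0.04, 0.2, 0.5, 0.9, 1.0]
        for size in range(1, 7):
            for _ in range(30):
                p = rng.choice(grid, size=size)
                assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)


class TestSignRecovery:
    def test_behavioral_signs_recovered_at_study_scale(self):
        """Rate negative, residual MAD positive, interaction negative, in
        >= 90% of 20 replicates at the full 57 x 300 cohort size."""
        from rhythmeg.studies import behavioral_sign_recovery

        out = behavioral_sign_recovery(n_replicates=20, seed=20260926)
        assert out["agreement_rate"] >= 0.90


class TestSlopeContrast:
    def _fit(self, rng, interaction=True, slope_by_level=None):
        n = 3000
        levels = np.array([5.0, 11.0, 16.0])
        lev = rng.choice(levels, size=n)
        mad = rng.standard_normal(n)
        if slope_by_level is None:
            slope_by_level = {5.0: 0.5, 11.0: 0.5, 16.0: 0.5} \
                if not interaction else {5.0: 0.2, 11.0: 0.5, 16.0: 0.8}
        eta = 0.2 + np.vectorize(slope_by_level.get)(lev) * mad
        y = rng.beta(expit(eta) * 40, (1 - expit(eta)) * 40)
        lev_c = lev - lev.mean()
        design = pd.DataFrame({"mad": mad, "lev_c": lev_c,
                               "mad:lev_c": mad * lev_c})
        fit = beta_regression_fit(design, y)
        modifiers = {float(l): {"mad:lev_c": float(l - lev.mean())}
                     for l in levels}
        return fit, modifiers

    def test_no_interaction_means_equal_slopes(self, rng):
        fit, modifiers = self._fit(rng, interaction=False)
        # zero out the interaction weights: identical linear combinations
        flat = {k: {"mad:lev_c": 0.0} for k in modifiers}
        slopes, diffs = slope_contrast(fit, "mad", flat)
        assert np.allclose(slopes["slope"], slopes["slope"].iloc[0])
        assert np.allclose(diffs["difference"], 0.0, atol=1e-12)

    def test_recovers_level_dependent_slopes(self, rng):
        truth = {5.0: 0.2, 11.0: 0.5, 16.0: 0.8}
        fit, modifiers = self._fit(rng, slope_by_level=truth)
        slopes, _ = slope_contrast(fit, "mad", modifiers)
        for _, row in slopes.iterrows():
            assert row["slope"] == pytest.approx(truth[row["level"]], abs=0.1)

    def test_self_contrast_is_zero(self, rng):
        fit, modifiers = self._fit(rng)
        lev = list(modifiers)[0]
        slopes, diffs = slope_contrast(
            fit, "mad", {"a": modifiers[lev], "b": modifiers[lev]})
        assert len(diffs) == 1
        assert np.allclose(diffs["difference"], 0.0)

    def test_unknown_term_rejected(self, rng):
        fit, _ = self._fit(rng)
        with pytest.raises(ValueError):
            slope_contrast(fit, "nope", {1.0: {}})


class TestFitReport:
    def test_writes_table_and_report(self, tmp_path, rng):
        from rhythmeg.stats import write_fit_report

        design = pd.DataFrame({"x": rng.standard_normal(300)})
        data = gen_behavior(design, BehaviorGenSpec(
            fixed_coefficients={"intercept": 0.2, "x": 0.5}, seed=9))
        fit = beta_regression_fit(design, data["score"])
        csv_path = tmp_path / "coefs.csv"
        json_path = tmp_path / "fit.json"
        table = write_fit_report(fit, csv_path, json_path, meta={"seed": 9})
        assert {"term", "estimate", "se", "p", "q"} <= set(table.columns)
        back = pd.read_csv(csv_path)
        assert list(back["term"]) == ["intercept", "x"]
        import json
        report = json.loads(json_path.read_text())
        assert report["converged"] and report["seed"] == 9
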