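"""Design encoding, evidence-maximised BLR, deviations, metrics, attribution."""
import numpy as np
import pandas as pd
import pytest

from fmrinorm import (
    build_design,
    compute_deviations,
    encode_design,
    evaluate_model,
    fit_blr,
    log_evidence,
    predict_blr,
    raw_covariate_columns,
    stratified_half_split,
    structure_coefficients,
)
from fmrinorm.simulate import sample_covariates

from conftest import dataset_from_matrix


def _design_1d(x, training=None):
    return build_design(pd.DataFrame({"x": x}), continuous=["x"], training=training)


class TestSplit:
    def test_even_and_odd_site_sizes(self):
        cov = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(10)],
                "site": ["a"] * 4 + ["b"] * 6,
            }
        )
        train, test = stratified_half_split(cov, seed=0)
        assert len(train) == 5 and len(test) == 5
        assert sum(s.startswith("s") and int(s[1:]) < 4 for s in train) == 2
        assert set(train) | set(test) == set(cov["subject_id"])
        assert set(train) & set(test) == set()

    def test_odd_count_gives_train_the_extra(self):
        cov = pd.DataFrame({"subject_id": list("abcde"), "site": ["x"] * 5})
        with pytest.raises(ValueError):
            stratified_half_split(cov.head(1), seed=0)
        cov["site"] = ["x"] * 3 + ["y"] * 2
        train, test = stratified_half_split(cov, seed=1)
        assert len(train) == 3 and len(test) == 2

    def test_determinism(self, two_sites):
        cov = sample_covariates(two_sites, seed=0)
        assert stratified_half_split(cov, seed=5) == stratified_half_split(cov, seed=5)

    def test_half_split_covers_cohort(self, two_sites):
        cov = sample_covariates(two_sites, seed=0)
        train, test = stratified_half_split(cov, seed=2)
        assert len(train) + len(test) == len(cov)


class TestEncodeDesign:
    def test_site_dummies_full_set(self, two_sites):
        cov = sample_covariates(two_sites, seed=1)
        design = encode_design(cov)
        assert design.site_dummy_columns == ["site_alpha", "site_bravo"]
        for site in two_sites:
            col = design.column_names.index(f"site_{site.site_id}")
            assert design.matrix[:, col].sum() == site.n_subjects

    def test_training_standardisation(self, two_sites):
        cov = sample_covariates(two_sites, seed=1)
        design = encode_design(cov)
        age = design.matrix[:, design.column_names.index("age")]
        assert abs(age.mean()) < 1e-10
        assert abs(age.std() - 1) < 1e-10

    def test_test_encoding_reuses_training_stats(self, two_sites):
        cov = sample_covariates(two_sites, seed=1)
        design = encode_design(cov)
        row = encode_design(cov.iloc[[5]], training=design)
        assert np.array_equal(row.matrix[0], design.matrix[5])

    def test_unseen_site_rejected(self, two_sites):
        cov = sample_covariates(two_sites, seed=1)
        design = encode_design(cov)
        with pytest.raises(ValueError, match="unseen"):
            encode_design(cov.assign(site="charlie"), training=design)

    def test_missing_covariate_is_hard_error(self, two_sites):
        cov = sample_covariates(two_sites, seed=1).drop(columns=["icv"])
        with pytest.raises(ValueError, match="missing"):
            encode_design(cov)
        cov2 = sample_covariates(two_sites, seed=1)
        cov2.loc[3, "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            encode_design(cov2)


class TestFitBLR:
    def test_slope_recovery(self):
        """y = 2x + noise(sd 0.1): the de-standardised slope lands in [1.9, 2.1]."""
        rng = np.random.default_rng(10)
        x = rng.uniform(-1, 1, size=200)
        y = 2.0 * x + rng.normal(0, 0.1, size=200)
        fit = fit_blr(_design_1d(x), dataset_from_matrix(y[:, None]))
        slope = fit.coefficients_raw()["x"].iloc[0]
        assert 1.9 < slope < 2.1

    def test_flat_prior_limit_equals_least_squares(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((60, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(0, 0.5, 60)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        design = build_design(df, continuous=["a", "b", "c"])
        fit = fit_blr(design, dataset_from_matrix(y[:, None]), fixed_alpha=1e-10)
        ys = (y - y.mean()) / y.std()
        ls, *_ = np.linalg.lstsq(design.matrix, ys, rcond=None)
        assert np.allclose(fit.coef[:, 0], ls, atol=1e-6)

    def test_ridge_equivalence(self):
        """Posterior mean equals the ridge solution with penalty alpha/beta."""
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(12)
        X = rng.standard_normal((50, 4))
        y = X @ np.array([0.5, 0.0, -1.0, 0.3]) + rng.normal(0, 0.8, 50)
        df = pd.DataFrame(X, columns=list("abcd"))
        design = build_design(df, continuous=list("abcd"))
        alpha, beta = 2.5, 4.0
        fit = fit_blr(design, dataset_from_matrix(y[:, None]),
                      fixed_alpha=alpha, fixed_beta=beta)
        ys = (y - y.mean()) / y.std()
        ridge = Ridge(alpha=alpha / beta, fit_intercept=False).fit(design.matrix, ys)
        assert np.allclose(fit.coef[:, 0], ridge.coef_, atol=1e-8)

    def test_evidence_beats_surrounding_grid(self):
        """The optimised (alpha, beta) dominate an 11x11 surrounding grid."""
        rng = np.random.default_rng(13)
        x = rng.standard_normal(120)
        y = 0.8 * x + rng.normal(0, 0.6, 120)
        design = _design_1d(x)
        fit = fit_blr(design, dataset_from_matrix(y[:, None]),
                      rtol=1e-12, max_iter=5000)
        ys = (y - y.mean()) / y.std()
        best = log_evidence(design.matrix, ys, fit.alpha[0], fit.beta[0])
        factors = np.logspace(-0.5, 0.5, 11)
        grid = [
            log_evidence(design.matrix, ys, fit.alpha[0] * fa, fit.beta[0] * fb)
            for fa in factors
            for fb in factors
        ]
        assert best >= max(grid) - 1e-6 * abs(best)

    def test_evidence_never_decreases(self, small_reference):
        cov, truth, data = small_reference
        design = encode_design(cov)
        fit = fit_blr(design, data, keep_path=True, max_iter=40)
        path = np.stack(fit.evidence_path)  # (iters, V)
        diffs = np.diff(path, axis=0)
        assert np.all(diffs >= -1e-8 * np.abs(path[:-1]))

    def test_rank_deficient_design_handled_by_prior(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(80)
        df = pd.DataFrame({"a": x, "b": x})  # perfectly collinear
        design = build_design(df, continuous=["a", "b"])
        y = x + rng.normal(0, 0.5, 80)
        fit = fit_blr(design, dataset_from_matrix(y[:, None]))
        assert np.isfinite(fit.coef).all()

    def test_needs_more_subjects_than_columns(self):
        x = np.arange(3.0)
        with pytest.raises(ValueError, match="n_subjects > p_design"):
            fit_blr(_design_1d(x[:2]), dataset_from_matrix(np.zeros((2, 1))))


class TestPredictAndDeviations:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(15)
        n, V = 400, 40
        x = rng.standard_normal(n)
        W = rng.normal(0, 0.8, size=(1, V))
        Y = np.outer(x, W[0]) + 1.5 + rng.normal(0, 0.7, size=(n, V))
        design = _design_1d(x)
        fit = fit_blr(design, dataset_from_matrix(Y))
        return rng, x, W, design, fit

    def test_predictive_variance_at_least_noise_floor(self, fitted):
        _, x, _, design, fit = fitted
        _, var = predict_blr(fit, design)
        floor = fit.y_sd**2 / fit.beta
        assert np.all(var >= floor[None, :] - 1e-12)

    def test_variance_shrinks_to_noise_floor_at_large_n(self):
        rng = np.random.default_rng(16)
        n = 5000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.normal(0, 1.0, n)
        design = _design_1d(x)
        fit = fit_blr(design, dataset_from_matrix(y[:, None]))
        _, var = predict_blr(fit, design)
        floor = fit.y_sd[0] ** 2 / fit.beta[0]
        assert np.all(var <= 1.05 * floor)

    def test_training_predictions_equal_ridge_fit(self):
        """Predicting the training design reproduces ridge fitted values with
        penalty alpha/beta (after de-standardisation)."""
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(26)
        x = rng.standard_normal(80)
        y = 1.2 * x + rng.normal(0, 0.5, 80)
        design = _design_1d(x)
        fit = fit_blr(design, dataset_from_matrix(y[:, None]))
        mean, _ = predict_blr(fit, design)
        ys = (y - y.mean()) / y.std()
        ridge = Ridge(alpha=fit.alpha[0] / fit.beta[0], fit_intercept=False)
        fitted_vals = ridge.fit(design.matrix, ys).predict(design.matrix)
        assert np.allclose(mean[:, 0], fitted_vals * y.std() + y.mean(), atol=1e-8)

    def test_zero_residual_gives_zero_z(self, fitted):
        _, x, _, design, fit = fitted
        mean, var = predict_blr(fit, design)
        ds = dataset_from_matrix(mean)
        dev = compute_deviations(fit, design, ds)
        assert np.allclose(dev.Z, 0.0)

    def test_heldout_calibration(self):
        """On held-out data from the true process, Z has mean ~0, var ~1 and
        the |Z| > 2.6 tail frequency matches 2*Phi(-2.6)."""
        from scipy.stats import norm

        rng = np.random.default_rng(17)
        n_train, n_test, V = 2000, 2000, 20
        x = rng.standard_normal(n_train + n_test)
        W = rng.normal(0, 0.8, size=V)
        Y = np.outer(x, W) + rng.normal(0, 1.0, size=(n_train + n_test, V))
        design_tr = _design_1d(x[:n_train])
        fit = fit_blr(design_tr, dataset_from_matrix(Y[:n_train]))
        design_te = _design_1d(x[n_train:], training=design_tr)
        dev = compute_deviations(fit, design_te, dataset_from_matrix(Y[n_train:]))
        assert np.all(np.abs(dev.Z.mean(axis=0)) < 0.1)
        assert np.all((dev.Z.var(axis=0) > 0.85) & (dev.Z.var(axis=0) < 1.15))
        expected = 2 * norm.cdf(-2.6)
        observed = np.mean(np.abs(dev.Z) > 2.6)
        assert abs(observed - expected) < 0.004

    def test_column_mismatch_rejected(self, fitted):
        _, x, _, design, fit = fitted
        other = build_design(pd.DataFrame({"z": x}), continuous=["z"])
        with pytest.raises(ValueError, match="columns"):
            predict_blr(fit, other)


class TestEvaluate:
    def test_constant_predictor_gives_zero_explained_variance(self):
        rng = np.random.default_rng(18)
        n = 300
        y = rng.standard_normal((n, 3)) + 5.0
        df = pd.DataFrame(index=range(n))
        design = build_design(df, continuous=[])  # intercept only
        fit = fit_blr(design, dataset_from_matrix(y))
        rep = evaluate_model(fit, design, dataset_from_matrix(y))
        assert np.allclose(rep.explained_variance, 0.0, atol=1e-8)
        assert np.all(rep.smse >= 1.0 - 1e-8)

    def test_noiseless_data(self):
        rng = np.random.default_rng(19)
        x = rng.standard_normal(100)
        y = 3.0 * x + 1.0
        design = _design_1d(x)
        fit = fit_blr(design, dataset_from_matrix(y[:, None]))
        rep = evaluate_model(fit, design, dataset_from_matrix(y[:, None]))
        assert rep.explained_variance[0] == pytest.approx(1.0, abs=1e-6)
        assert rep.smse[0] == pytest.approx(0.0, abs=1e-6)

    def test_explained_variance_matches_analytic_r2(self, small_mask):
        """Held-out EV within ±0.05 of signalVar/(signalVar+noiseVar)."""
        from fmrinorm.simulate import (
            SiteSpec, generate_activation, make_truth_model, truth_signal,
        )

        sites = [
            SiteSpec("a", 1000, (20.0, 60.0), 0.5, 0.8, True, 176, 150.0, 3,
                     "match_faces", "NimStim"),
            SiteSpec("b", 1000, (25.0, 75.0), 0.6, 2.0, False, 195, 280.0, 4,
                     "match_expression", "Ekman"),
        ]
        cov = sample_covariates(sites, seed=20)
        truth = make_truth_model(sites, small_mask, seed=20)
        data = generate_activation(cov, truth, seed=20)
        train, test = stratified_half_split(cov, seed=20)
        cov_tr = cov[cov.subject_id.isin(train)]
        cov_te = cov[cov.subject_id.isin(test)]
        design_tr = encode_design(cov_tr)
        fit = fit_blr(design_tr, data.subset(list(cov_tr.subject_id)))
        rep = evaluate_model(
            fit, encode_design(cov_te, training=design_tr),
            data.subset(list(cov_te.subject_id)),
        )
        signal = truth_signal(cov_te, truth)
        r2 = signal.var(axis=0) / (signal.var(axis=0) + truth.noise_sd**2)
        diff = np.abs(rep.explained_variance - r2)
        assert diff.mean() < 0.05
        assert np.mean(diff < 0.05) >= 0.90  # sampling noise at n=1000 per voxel

    def test_zero_test_variance_flagged(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(50)
        y = x + rng.normal(0, 0.3, 50)
        design = _design_1d(x)
        fit = fit_blr(design, dataset_from_matrix(y[:, None]))
        const = dataset_from_matrix(np.full((50, 1), 2.0))
        rep = evaluate_model(fit, design, const)
        assert rep.undefined.tolist() == [0]
        assert np.isnan(rep.explained_variance[0])


class TestInvariance:
    def test_metrics_invariant_to_subject_and_voxel_order(self, small_reference):
        cov, truth, data = small_reference
        design = encode_design(cov)
        fit = fit_blr(design, data)
        dev = compute_deviations(fit, design, data)
        rng = np.random.default_rng(22)
        perm_v = rng.permutation(data.n_voxels)
        # voxel reordering permutes the fit identically
        from fmrinorm import ActivationDataset

        data_p = ActivationDataset(
            data.data[:, perm_v], data.mask, data.subject_ids, data.contrast
        )
        fit_p = fit_blr(design, data_p)
        dev_p = compute_deviations(fit_p, design, data_p)
        assert np.allclose(dev_p.Z, dev.Z[:, perm_v], atol=1e-10)


class TestStructureCoefficients:
    def test_single_covariate_has_unit_correlation(self):
        rng = np.random.default_rng(23)
        x = rng.standard_normal(150)
        Y = np.outer(x, [1.0, -2.0, 0.5]) + rng.normal(0, 0.5, (150, 3))
        design = _design_1d(x)
        fit = fit_blr(design, dataset_from_matrix(Y))
        pred, _ = predict_blr(fit, design)
        sc = structure_coefficients(pd.DataFrame({"x": x}), pred)
        assert np.allclose(np.abs(sc.rho[0]), 1.0, atol=1e-8)

    def test_complementary_dummies_flip_sign(self, small_reference):
        cov, truth, data = small_reference
        design = encode_design(cov)
        fit = fit_blr(design, data)
        pred, _ = predict_blr(fit, design)
        raw = raw_covariate_columns(cov)
        sc = structure_coefficients(raw, pred)
        i = sc.columns.index("site_alpha")
        j = sc.columns.index("site_bravo")
        assert np.allclose(sc.rho[i], -sc.rho[j], atol=1e-10)

    def test_matches_brute_force_correlations(self):
        rng = np.random.default_rng(24)
        X = np.linalg.qr(rng.standard_normal((40, 3)))[0]  # orthogonal columns
        pred = X @ rng.standard_normal((3, 6)) + rng.normal(0, 0.1, (40, 6))
        raw = pd.DataFrame(X, columns=["a", "b", "c"])
        sc = structure_coefficients(raw, pred)
        for jcol in range(3):
            for v in range(6):
                brute = np.corrcoef(X[:, jcol], pred[:, v])[0, 1]
                assert sc.rho[jcol, v] == pytest.approx(brute, abs=1e-8)

    def test_zero_variance_column_flagged(self):
        rng = np.random.default_rng(25)
        pred = rng.standard_normal((30, 4))
        raw = pd.DataFrame({"const": np.ones(30), "x": rng.standard_normal(30)})
        sc = structure_coefficients(raw, pred)
        assert sc.undefined_columns == ["const"]
        assert np.isnan(sc.rho[0]).all()
        assert np.isfinite(sc.rho[1]).all()
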