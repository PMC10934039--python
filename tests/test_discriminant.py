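import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln

from hrv3state import (
    ConfusionTable,
    classify_cohort,
    confusion_report,
    d_score,
    fit_lda,
    hotelling_p,
    mahalanobis,
    sens_spec,
    separation,
)
from hrv3state.discriminant import DiscriminantModel, default_ridge
from hrv3state.errors import ModelError, ValidationError


def gaussian_groups(mu_f, mu_l, cov, n, seed=0):
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(np.atleast_2d(cov))
    p = len(mu_f)
    Xf = rng.standard_normal((n, p)) @ L.T + mu_f
    Xl = rng.standard_normal((n, p)) @ L.T + mu_l
    return Xf, Xl


class TestFitLDA:
    def test_univariate_closed_form(self):
        """Means +/-1, pooled variance 1 -> coefficient 2, discriminant point 0."""
        rng = np.random.default_rng(1)
        Xf = (1.0 + rng.standard_normal(4000)).reshape(-1, 1)
        Xl = (-1.0 + rng.standard_normal(4000)).reshape(-1, 1)
        # exact construction: enforce sample means and variance analytically
        Xf = (Xf - Xf.mean()) / Xf.std(ddof=1) + 1.0
        Xl = (Xl - Xl.mean()) / Xl.std(ddof=1) - 1.0
        m = fit_lda(Xf, Xl)
        assert m.coefficients[0] == pytest.approx(2.0, rel=1e-3)
        assert m.discriminant_point == pytest.approx(0.0, abs=1e-9)

    def test_bivariate_identity_covariance(self):
        """Identity covariance, means (1,0) and (0,0) -> coefficients (1,0), point 0.5."""
        rng = np.random.default_rng(2)

        def whitened(n, mean):
            Z = rng.standard_normal((n, 2))
            Z = Z - Z.mean(axis=0)
            Z = Z @ np.linalg.inv(np.linalg.cholesky(np.cov(Z, rowvar=False))).T
            return Z + mean

        # each group whitened exactly -> pooled covariance is the identity
        Xf = whitened(3000, [1.0, 0.0])
        Xl = whitened(3000, [0.0, 0.0])
        m = fit_lda(Xf, Xl)
        np.testing.assert_allclose(m.coefficients, [1.0, 0.0], atol=1e-6)
        assert m.discriminant_point == pytest.approx(0.5, abs=1e-6)

    def test_identical_groups_degenerate(self):
        X = np.random.default_rng(3).standard_normal((10, 3))
        m = fit_lda(X, X.copy())
        assert m.degenerate
        np.testing.assert_array_equal(m.coefficients, 0.0)

    def test_singular_covariance_advises_ridge(self):
        X = np.ones((5, 3))
        X[:, 0] = np.arange(5)
        Y = X + [0.0, 1.0, 1.0]
        with pytest.raises(ModelError, match="ridge"):
            fit_lda(X, Y, ridge=0.0)

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            fit_lda(np.ones((1, 2)), np.ones((5, 2)))


class TestDScore:
    @pytest.fixture
    def model(self):
        Xf, Xl = gaussian_groups([2.0, 0.0], [0.0, 0.0], np.eye(2), 200, seed=4)
        return fit_lda(Xf, Xl, group_pair=("PPD", "AJD"))

    def test_sign_convention_at_group_means(self, model):
        assert d_score(model, model.means["PPD"]) > 0
        assert d_score(model, model.means["AJD"]) < 0

    def test_zero_at_midpoint(self, model):
        mid = (model.means["PPD"] + model.means["AJD"]) / 2
        assert abs(d_score(model, mid)) < 1e-9

    def test_training_means_project_to_half_squared_md(self, model):
        md = mahalanobis(model)
        assert d_score(model, model.means["PPD"]) == pytest.approx(md**2 / 2, rel=1e-9)
        assert d_score(model, model.means["AJD"]) == pytest.approx(-(md**2) / 2, rel=1e-9)

    def test_length_mismatch(self, model):
        with pytest.raises(ValidationError):
            d_score(model, np.ones(5))


class TestClassifyAndSensSpec:
    def test_means_classified_perfectly(self):
        Xf, Xl = gaussian_groups([5.0], [0.0], [[1.0]], 50, seed=5)
        m = fit_lda(Xf, Xl, group_pair=("PPD", "AJD"))
        X = np.vstack([np.full((3, 1), 5.0), np.zeros((3, 1))])
        ct = classify_cohort(m, X, ["PPD"] * 3 + ["AJD"] * 3)
        assert ct.fn == 0 and ct.fp == 0

    def test_midpoint_tie_counts_negative(self):
        Xf, Xl = gaussian_groups([2.0], [0.0], [[1.0]], 100, seed=6)
        m = fit_lda(Xf, Xl, group_pair=("PPD", "AJD"))
        mid = (m.means["PPD"] + m.means["AJD"]) / 2
        ct = classify_cohort(m, mid.reshape(1, -1), ["PPD"])
        assert ct.fn == 1 and ct.tp == 0

    def test_empty_cohort_errors(self):
        Xf, Xl = gaussian_groups([2.0], [0.0], [[1.0]], 10, seed=7)
        m = fit_lda(Xf, Xl)
        with pytest.raises(ValidationError):
            classify_cohort(m, np.empty((0, 1)), [])

    def test_foreign_label_errors(self):
        Xf, Xl = gaussian_groups([2.0], [0.0], [[1.0]], 10, seed=8)
        m = fit_lda(Xf, Xl, group_pair=("PPD", "AJD"))
        with pytest.raises(ValidationError):
            classify_cohort(m, np.zeros((1, 1)), ["control"])

    def test_published_confusion_arithmetic(self):
        ct = ConfusionTable(tp=9, fn=3, fp=3, tn=30)
        sens, spec = sens_spec(ct)
        assert sens == 75.0 and spec == 90.9

    def test_empty_margin_errors(self):
        with pytest.raises(ValidationError):
            sens_spec(ConfusionTable(tp=0, fn=0, fp=1, tn=1))

    def test_report_contains_published_rates(self):
        ct = ConfusionTable(tp=9, fn=3, fp=3, tn=30)
        text = confusion_report(ct, ("PPD", "AJD"))
        assert "75.0%" in text and "90.9%" in text


class TestMahalanobis:
    def test_identity_covariance_unit_distance(self):
        Xf, Xl = gaussian_groups([1.0, 0.0], [0.0, 0.0], np.eye(2), 2000, seed=9)
        Xf = Xf - Xf.mean(axis=0) + [1.0, 0.0]
        Xl = Xl - Xl.mean(axis=0)
        m = fit_lda(Xf, Xl)
        md = mahalanobis(m)
        # pooled covariance is near-identity at n = 2000
        assert md == pytest.approx(1.0, rel=0.05)

    def test_identical_means_zero(self):
        X = np.random.default_rng(10).standard_normal((20, 2))
        m = fit_lda(X, X.copy())
        assert mahalanobis(m) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Xf = rng.standard_normal((15, 3)) + rng.uniform(-2, 2, 3)
        Xl = rng.standard_normal((17, 3))
        m = fit_lda(Xf, Xl)
        diff = m.means[m.group_pair[0]] - m.means[m.group_pair[1]]
        oracle = float(np.sqrt(diff @ np.linalg.inv(m.pooled_cov) @ diff))
        assert mahalanobis(m) == pytest.approx(oracle, abs=1e-9)


class TestHotelling:
    def test_zero_distance_gives_p_one(self):
        s = hotelling_p(0.0, 20, 20, 2)
        assert s.t2 == 0.0 and s.p == pytest.approx(1.0)

    def test_p_decreases_with_md(self):
        ps = [hotelling_p(md, 20, 20, 2).p for md in (0.5, 1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_f_tail_quadrature(self):
        """p equals direct quadrature of the F(2, 37) density above the statistic."""
        n1 = n2 = 20
        p_dim = 2
        md = 1.0
        t2 = (n1 * n2 / (n1 + n2)) * md**2
        d2 = n1 + n2 - p_dim - 1
        f_stat = t2 * d2 / (p_dim * (n1 + n2 - 2))

        def f_pdf(x, d1, d2):
            logc = (gammaln((d1 + d2) / 2) - gammaln(d1 / 2) - gammaln(d2 / 2)
                    + (d1 / 2) * np.log(d1 / d2))
            return np.exp(logc + (d1 / 2 - 1) * np.log(x)
                          - ((d1 + d2) / 2) * np.log(1 + d1 * x / d2))

        tail, _ = integrate.quad(f_pdf, f_stat, np.inf, args=(p_dim, d2))
        assert hotelling_p(md, n1, n2, p_dim).p == pytest.approx(tail, abs=1e-6)

    def test_insufficient_df(self):
        with pytest.raises(ValidationError):
            hotelling_p(1.0, 3, 3, 12)


class TestInvariances:
    def test_affine_rescaling_invariance(self):
        """Labels and Md are unchanged by invertible affine feature maps (ridge 0)."""
        rng = np.random.default_rng(11)
        Xf = rng.standard_normal((30, 4)) + [2, 0, 1, 0]
        Xl = rng.standard_normal((30, 4))
        A = rng.uniform(0.5, 2.0, (4, 4)) + 4 * np.eye(4)
        shift = rng.uniform(-3, 3, 4)
        m1 = fit_lda(Xf, Xl, group_pair=("f", "l"))
        m2 = fit_lda(Xf @ A + shift, Xl @ A + shift, group_pair=("f", "l"))
        X = np.vstack([Xf, Xl])
        labels = ["f"] * 30 + ["l"] * 30
        c1 = classify_cohort(m1, X, labels)
        c2 = classify_cohort(m2, X @ A + shift, labels)
        assert (c1.tp, c1.fn, c1.fp, c1.tn) == (c2.tp, c2.fn, c2.fp, c2.tn)
        assert mahalanobis(m1) == pytest.approx(mahalanobis(m2), rel=1e-8)

    def test_well_separated_cohort_high_accuracy(self):
        """Well-separated groups (Md >= 3) at n = 200/group classify at >= 95%.

        Resubstitution accuracy approaches Phi(Md/2); Md = 4 leaves sampling
        headroom above the 95% bar.
        """
        mu_f = np.zeros(6)
        mu_f[0] = 4.0  # Mahalanobis distance 4 under identity covariance
        Xf, Xl = gaussian_groups(mu_f, np.zeros(6), np.eye(6), 200, seed=12)
        m = fit_lda(Xf, Xl, group_pair=("f", "l"))
        ct = classify_cohort(m, np.vstack([Xf, Xl]), ["f"] * 200 + ["l"] * 200)
        sens, spec = sens_spec(ct)
        assert sens >= 95.0 and spec >= 95.0

    def test_sklearn_cross_check(self):
        """Decision boundary agrees with scikit-learn's LDA on the same data."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(13)
        Xf = rng.standard_normal((40, 5)) + [1.5, 0, 0, 0.5, 0]
        Xl = rng.standard_normal((45, 5))
        m = fit_lda(Xf, Xl, group_pair=("f", "l"))
        X = np.vstack([Xf, Xl])
        ours = np.where(np.atleast_1d(d_score(m, X)) > 0, "f", "l")
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(
            X, ["f"] * 40 + ["l"] * 45
        )
        agreement = np.mean(ours == sk.predict(X))
        assert agreement == 1.0


def test_model_json_roundtrip(tmp_path):
    Xf, Xl = gaussian_groups(np.ones(12), np.zeros(12), np.eye(12), 30, seed=14)
    m = fit_lda(Xf, Xl, group_pair=("PPD", "AJD"), ridge=default_ridge(np.eye(12)))
    path = tmp_path / "model.json"
    m.to_json(path)
    back = DiscriminantModel.from_json(path)
    np.testing.assert_allclose(back.coefficients, m.coefficients)
    assert back.group_pair == m.group_pair
    assert back.discriminant_point == pytest.approx(m.discriminant_point)
    x = np.random.default_rng(15).standard_normal(12)
    assert d_score(back, x) == pytest.approx(d_score(m, x))


def test_separation_reports_md_and_p():
    Xf, Xl = gaussian_groups([2.0, 0.0], [0.0, 0.0], np.eye(2), 40, seed=16)
    m = fit_lda(Xf, Xl, group_pair=("f", "l"))
    s = separation(m)
    assert s.md > 1.0 and 0.0 < s.p < 0.01
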