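import numpy as np
import pytest
from scipy.optimize import minimize

from epicad import ocsvm
from epicad.features import FeatureVectorField
from epicad.ocsvm import (
    ModelBank,
    default_nu_grid,
    default_sigma_grid,
    estimate_loo_fpr,
    rbf_kernel,
    score_subject,
    select_hyperparameters,
    signed_distance,
    train_bank,
    train_ocsvm,
)


def qp_oracle_decision(X, nu, sigma, test_points):
    """Independent generic QP solution of the one-class dual (SLSQP)."""
    n = len(X)
    C = 1.0 / (nu * n)
    d2 = ((X[:, None] - X[None, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2 * sigma**2))
    res = minimize(
        lambda a: 0.5 * a @ K @ a, np.full(n, 1.0 / n), jac=lambda a: K @ a,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                      "jac": lambda a: np.ones(n)}],
        method="SLSQP", options={"ftol": 1e-14, "maxiter": 1000})
    assert res.success
    a = res.x
    g = K @ a
    eps = 1e-7 * max(C, 1.0)
    free = (a > eps) & (a < C - eps)
    if free.any():
        rho = g[free].mean()
    else:
        rho = 0.5 * (g[a >= C - eps].max() + g[a <= eps].min())
    w_norm = np.sqrt(a @ g)
    k = np.exp(-((X[None, :, :] - test_points[:, None, :]) ** 2).sum(-1)
               / (2 * sigma**2))
    return (k @ a - rho) / w_norm


def random_field_cohort(rng, n_subjects=10, shape=(6, 6, 6)):
    mask = np.ones(shape, bool)
    return [FeatureVectorField(values=rng.standard_normal((mask.sum(), 2)),
                               mask=mask) for _ in range(n_subjects)]


class TestRbfKernel:
    def test_zero_distance_gives_one(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], 0.7) == 1.0

    def test_monotone_decreasing_in_distance(self):
        vals = [rbf_kernel([0, 0], [d, 0], 1.0) for d in (0.5, 1.0, 2.0, 10.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-6

    def test_characteristic_scale(self):
        # squared distance 2 sigma^2 -> exp(-1)
        sigma = 1.3
        x = np.array([0.0, 0.0])
        y = np.array([np.sqrt(2) * sigma, 0.0])
        assert rbf_kernel(x, y, sigma) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([0], [1], 0.0)


class TestTrainOcsvm:
    def test_duplication_symmetry(self, rng):
        X = rng.standard_normal((15, 2))
        m1 = train_ocsvm(X, nu=0.3, sigma=1.0)
        m2 = train_ocsvm(np.vstack([X, X]), nu=0.3, sigma=1.0)
        T = rng.standard_normal((25, 2))
        assert np.allclose(signed_distance(m1, T), signed_distance(m2, T),
                           atol=1e-6)

    def test_dual_feasibility(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = int(r.integers(5, 41))
            nu = float(r.uniform(0.05, 0.95))
            X = r.standard_normal((n, 2))
            m = train_ocsvm(X, nu=nu, sigma=1.0)
            C = 1.0 / (nu * n)
            assert m.dual_coefficients.min() >= -1e-12
            assert m.dual_coefficients.max() <= C + 1e-9
            assert m.dual_coefficients.sum() == pytest.approx(1.0, abs=1e-6)
            assert m.w_norm > 0

    def test_nu_property_two_sided_monte_carlo(self):
        # over 200 random training sets: outlier fraction <= nu + 1/n and
        # support-vector fraction >= nu - 1/n
        n, nu = 37, 0.2
        bad_out = bad_sv = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            X = r.standard_normal((n, 2))
            m = train_ocsvm(X, nu=nu, sigma=1.0)
            d = signed_distance(m, X)
            if np.mean(d < -1e-8) > nu + 1.0 / n:
                bad_out += 1
            if len(m.dual_coefficients) / n < nu - 1.0 / n:
                bad_sv += 1
        assert bad_out == 0
        assert bad_sv == 0

    def test_margin_support_vector_has_zero_distance(self, rng):
        X = rng.standard_normal((20, 2))
        nu = 0.4
        m = train_ocsvm(X, nu=nu, sigma=1.2)
        C = 1.0 / (nu * 20)
        a = m.dual_coefficients
        margin = (a > 1e-6) & (a < C - 1e-6)
        assert margin.any()
        d = signed_distance(m, m.support_vectors[margin])
        assert np.abs(d).max() < 1e-6

    def test_far_point_limit(self, rng):
        X = rng.standard_normal((12, 2))
        m = train_ocsvm(X, nu=0.3, sigma=0.8)
        far = signed_distance(m, np.array([1e4, -1e4]))
        assert far == pytest.approx(-m.rho / m.w_norm, rel=1e-9)

    def test_scale_equivariance(self, rng):
        # scaling features and sigma together leaves the kernel, hence all
        # decision values, unchanged
        X = rng.standard_normal((18, 2))
        T = rng.standard_normal((7, 2))
        c = 3.7
        m1 = train_ocsvm(X, nu=0.25, sigma=1.1)
        m2 = train_ocsvm(c * X, nu=0.25, sigma=c * 1.1)
        assert np.allclose(signed_distance(m1, T), signed_distance(m2, c * T),
                           atol=1e-8)

    def test_invalid_nu_rejected(self, rng):
        with pytest.raises(ValueError):
            train_ocsvm(rng.standard_normal((10, 2)), nu=0.0, sigma=1.0)

    def test_qp_oracle_agreement(self):
        for seed in range(30):
            r = np.random.default_rng(100 + seed)
            n = int(r.integers(5, 41))
            nu = float(r.uniform(0.05, 0.9))
            sigma = float(r.uniform(0.5, 3.0))
            X = r.standard_normal((n, 2))
            T = r.standard_normal((8, 2))
            m = train_ocsvm(X, nu=nu, sigma=sigma)
            assert np.allclose(signed_distance(m, T),
                               qp_oracle_decision(X, nu, sigma, T), atol=1e-6)

    def test_libsvm_cross_check(self, rng):
        # libsvm's one-class decision values equal ours up to the nu*n dual
        # scaling (and no geometric normalization)
        from sklearn.svm import OneClassSVM

        X = rng.standard_normal((30, 2))
        nu, sigma = 0.25, 1.4
        m = train_ocsvm(X, nu=nu, sigma=sigma)
        sk = OneClassSVM(nu=nu, gamma=1.0 / (2 * sigma**2), tol=1e-9).fit(X)
        T = rng.standard_normal((10, 2))
        ours_unnormalized = signed_distance(m, T) * m.w_norm
        assert np.allclose(ours_unnormalized * nu * 30,
                           sk.decision_function(T), atol=1e-5)


class TestBank:
    def test_model_count_matches_mask(self, rng):
        fields = random_field_cohort(rng, n_subjects=8)
        bank = train_bank(fields, nu=0.2, sigma=1.0)
        assert bank.n_models == fields[0].n_voxels

    def test_chunked_equals_unchunked(self, rng):
        fields = random_field_cohort(rng, n_subjects=6)
        b1 = train_bank(fields, nu=0.3, sigma=1.0, chunk_size=7)
        b2 = train_bank(fields, nu=0.3, sigma=1.0, chunk_size=10_000)
        assert np.array_equal(b1.alphas, b2.alphas)
        assert np.array_equal(b1.rhos, b2.rhos)

    def test_retraining_is_deterministic(self, rng):
        fields = random_field_cohort(rng, n_subjects=6)
        b1 = train_bank(fields, nu=0.3, sigma=1.0)
        b2 = train_bank(fields, nu=0.3, sigma=1.0)
        s1 = score_subject(b1, fields[0])
        s2 = score_subject(b2, fields[0])
        assert np.array_equal(s1.scores, s2.scores)

    def test_constant_models_and_features_give_constant_map(self, rng):
        mask = np.ones((5, 5, 5), bool)
        base = rng.standard_normal((1, 2))
        fields = []
        for s in range(8):
            vals = np.tile(rng.standard_normal((1, 2)), (mask.sum(), 1))
            fields.append(FeatureVectorField(values=vals, mask=mask))
        bank = train_bank(fields, nu=0.3, sigma=1.0)
        smap = score_subject(bank, FeatureVectorField(
            values=np.tile(base, (mask.sum(), 1)), mask=mask))
        assert np.allclose(smap.scores, smap.scores[0])

    def test_scoring_training_subject_mostly_inlier(self, rng):
        fields = random_field_cohort(rng, n_subjects=20, shape=(8, 8, 8))
        nu = 0.1
        bank = train_bank(fields, nu=nu, sigma=1.0)
        frac_neg = np.mean([np.mean(score_subject(bank, f).scores < -1e-8)
                            for f in fields])
        assert frac_neg <= nu + 1.0 / 20

    def test_model_at_matches_map(self, rng):
        fields = random_field_cohort(rng, n_subjects=8)
        bank = train_bank(fields, nu=0.3, sigma=1.0)
        smap = score_subject(bank, fields[2])
        v = 17
        model = bank.model_at(v)
        assert signed_distance(model, fields[2].values[v]) == pytest.approx(
            smap.scores[v], abs=1e-9)

    def test_mask_mismatch_rejected(self, rng):
        fields = random_field_cohort(rng, n_subjects=4)
        bank = train_bank(fields, nu=0.3, sigma=1.0)
        other_mask = np.zeros((6, 6, 6), bool)
        other_mask[0] = True
        other = FeatureVectorField(
            values=rng.standard_normal((other_mask.sum(), 2)), mask=other_mask)
        with pytest.raises(ValueError):
            score_subject(bank, other)

    def test_save_load_round_trip(self, rng, tmp_path):
        fields = random_field_cohort(rng, n_subjects=6)
        bank = train_bank(fields, nu=0.3, sigma=1.0, provenance={"cohort": "x"})
        path = str(tmp_path / "bank.npz")
        ocsvm.save_bank(bank, path)
        back = ocsvm.load_bank(path)
        assert isinstance(back, ModelBank)
        assert np.array_equal(back.alphas, bank.alphas)
        assert back.provenance == {"cohort": "x"}
        s1 = score_subject(bank, fields[0])
        s2 = score_subject(back, fields[0])
        assert np.array_equal(s1.scores, s2.scores)


class TestLooAndSelection:
    def test_fpr_in_unit_interval_and_monotone_in_nu(self, rng):
        fields = random_field_cohort(rng, n_subjects=12, shape=(6, 6, 6))
        f_small = estimate_loo_fpr(fields, nu=0.03, sigma=1.0, n_voxels=150, seed=0)
        f_large = estimate_loo_fpr(fields, nu=0.5, sigma=1.0, n_voxels=150, seed=0)
        assert 0.0 <= f_small <= 1.0
        assert f_large > f_small

    def test_fpr_estimate_stabilizes_with_voxel_count(self, rng):
        fields = random_field_cohort(rng, n_subjects=10, shape=(12, 12, 12))
        f1 = estimate_loo_fpr(fields, nu=0.2, sigma=1.0, n_voxels=400, seed=1)
        f2 = estimate_loo_fpr(fields, nu=0.2, sigma=1.0, n_voxels=1600, seed=1)
        noise = 4 * np.sqrt(f2 * (1 - f2) / (400 * 10))
        assert abs(f1 - f2) < noise + 0.01

    def test_default_grids_span_printed_endpoints(self):
        nu = default_nu_grid()
        sg = default_sigma_grid()
        assert nu.size == 8 and sg.size == 8
        assert nu[0] == pytest.approx(0.01)
        assert nu[-1] == pytest.approx(0.56)
        assert sg[0] == pytest.approx(2.0**-4)
        assert sg[-1] == pytest.approx(2.0**4)
        # log-equal spacing
        assert np.allclose(np.diff(np.log10(nu)), np.diff(np.log10(nu))[0])
        assert np.allclose(np.diff(np.log2(sg)), np.diff(np.log2(sg))[0])

    def test_selection_returns_exhaustive_argmin(self, rng):
        fields = random_field_cohort(rng, n_subjects=10, shape=(6, 6, 6))
        nu_grid = [0.05, 0.2, 0.5]
        sigma_grid = [0.5, 1.0, 2.0]
        (nu, sigma), table = select_hyperparameters(
            fields, nu_grid, sigma_grid, n_voxels=100, seed=3, return_table=True)
        # exhaustive oracle: independently evaluate the LOO FPR per pair
        fprs = {(r["nu"], r["sigma"]): estimate_loo_fpr(
            fields, r["nu"], r["sigma"], n_voxels=100, seed=3) for r in table}
        best_fpr = min(fprs.values())
        assert fprs[(nu, sigma)] == best_fpr
        for r in table:
            assert r["loo_fpr"] == pytest.approx(fprs[(r["nu"], r["sigma"])])

    def test_empty_grid_rejected(self, rng):
        fields = random_field_cohort(rng, n_subjects=5)
        with pytest.raises(ValueError):
            select_hyperparameters(fields, [], [0.5], n_voxels=10)
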