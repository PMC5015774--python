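import itertools

import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from epicad.evaluation import (
    bootstrap_auc_ci,
    bootstrap_auc_diff_ci,
    conjunction_map,
    mip,
    roc_curve,
    tpr_at_fpr,
    univariate_tmap,
)
from epicad.volumes import AnalysisMask, Volume


def _full_mask(shape=(6, 6, 6)):
    return AnalysisMask(np.ones(shape, bool))


def concordance_auc(y, s):
    """Brute-force pairwise concordance count (ties count half)."""
    pos = s[y]
    neg = s[~y]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def bc_interval_oracle(boot, point, level=0.95):
    """Independent implementation of the bias-corrected percentile interval."""
    boot = np.asarray(boot, float)
    if boot.max() - boot.min() < 1e-12:
        return point, point
    frac = np.clip(np.mean(boot < point), 0.5 / boot.size, 1 - 0.5 / boot.size)
    z0 = ndtri(frac)
    a = 1.0 - level
    return (float(np.quantile(boot, ndtr(2 * z0 + ndtri(a / 2)))),
            float(np.quantile(boot, ndtr(2 * z0 + ndtri(1 - a / 2)))))


class TestRoc:
    def test_perfect_separation(self, rng):
        truth = np.zeros((6, 6, 6), bool)
        truth[:2] = True
        susp = np.where(truth, 10.0 + rng.random(truth.shape), rng.random(truth.shape))
        roc = roc_curve([Volume(susp)], [truth], _full_mask())
        assert roc.auc == 1.0
        assert roc.n_pos == truth.sum()

    def test_random_scores_near_chance(self, rng):
        truth = rng.random((12, 12, 12)) < 0.3
        susp = rng.standard_normal(truth.shape)
        roc = roc_curve([Volume(susp)], [truth], _full_mask((12, 12, 12)))
        assert abs(roc.auc - 0.5) < 0.05

    def test_auc_equals_pairwise_concordance(self, rng):
        shape = (14, 14, 14)  # 2744 voxels, brute-force tractable
        truth = rng.random(shape) < 0.1
        susp = rng.standard_normal(shape) + truth * 0.8
        susp = np.round(susp, 1)  # force ties
        roc = roc_curve([Volume(susp)], [truth], _full_mask(shape))
        assert roc.auc == pytest.approx(
            concordance_auc(truth.ravel(), susp.ravel()), abs=1e-12)

    def test_pooling_invariance(self, rng):
        shape = (8, 8, 8)
        truths = [rng.random(shape) < 0.2 for _ in range(3)]
        susps = [rng.standard_normal(shape) for _ in range(3)]
        pooled = roc_curve([Volume(s) for s in susps], truths, _full_mask(shape))
        concat_s = np.concatenate([s.ravel() for s in susps]).reshape(3 * 512, 1, 1)
        concat_t = np.concatenate([t.ravel() for t in truths]).reshape(3 * 512, 1, 1)
        direct = roc_curve([Volume(concat_s)], [concat_t],
                           AnalysisMask(np.ones(concat_s.shape, bool)))
        assert pooled.auc == pytest.approx(direct.auc, abs=1e-12)

    def test_single_class_rejected(self, rng):
        truth = np.zeros((4, 4, 4), bool)
        with pytest.raises(ValueError):
            roc_curve([Volume(rng.random((4, 4, 4)))], [truth], _full_mask((4, 4, 4)))


class TestTprAtFpr:
    def test_perfect_classifier_hits_one_everywhere(self, rng):
        truth = np.zeros((6, 6, 6), bool)
        truth[0] = True
        susp = np.where(truth, 2.0, 0.0)
        roc = roc_curve([Volume(susp)], [truth], _full_mask())
        assert tpr_at_fpr(roc) == [1.0, 1.0, 1.0]

    def test_monotone_across_targets(self, rng):
        truth = rng.random((10, 10, 10)) < 0.2
        susp = rng.standard_normal(truth.shape) + truth
        roc = roc_curve([Volume(susp)], [truth], _full_mask((10, 10, 10)))
        t1, t5, t10 = tpr_at_fpr(roc, [0.01, 0.05, 0.1])
        assert t1 <= t5 <= t10

    def test_agrees_with_direct_thresholding(self, rng):
        shape = (10, 10, 10)
        truth = rng.random(shape) < 0.2
        susp = rng.standard_normal(shape) + truth
        roc = roc_curve([Volume(susp)], [truth], _full_mask(shape))
        for target, got in zip([0.05], tpr_at_fpr(roc, [0.05])):
            # best achievable TPR among thresholds with FPR <= target
            best = 0.0
            for t in np.unique(susp):
                fpr = (susp[~truth] >= t).mean()
                if fpr <= target:
                    best = max(best, (susp[truth] >= t).mean())
            assert got == pytest.approx(best, abs=1e-12)

    def test_invalid_target_rejected(self, rng):
        truth = np.zeros((4, 4, 4), bool)
        truth[0] = True
        roc = roc_curve([Volume(rng.random((4, 4, 4)))], [truth],
                        _full_mask((4, 4, 4)))
        with pytest.raises(ValueError):
            tpr_at_fpr(roc, [1.5])


class TestBootstrap:
    def _subjects(self, rng, n=3, voxels=60, effect=1.0):
        scores, truths = [], []
        for _ in range(n):
            t = rng.random(voxels) < 0.3
            scores.append(rng.standard_normal(voxels) + effect * t)
            truths.append(t)
        return scores, truths

    def test_identical_subjects_zero_width(self, rng):
        s = rng.standard_normal(50)
        t = rng.random(50) < 0.4
        ci = bootstrap_auc_ci([s, s.copy(), s.copy()], [t, t.copy(), t.copy()],
                              n_boot=40, seed=0)
        assert ci.lower == ci.upper == ci.point_estimate

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        scores, truths = self._subjects(rng)
        ci = bootstrap_auc_ci(scores, truths, seed=0, exhaustive=True)
        boot = []
        for pick in itertools.product(range(3), repeat=3):
            y = np.concatenate([truths[i] for i in pick])
            s = np.concatenate([scores[i] for i in pick])
            boot.append(concordance_auc(y, s))
        point = concordance_auc(np.concatenate(truths), np.concatenate(scores))
        lo, hi = bc_interval_oracle(boot, point)
        assert ci.n_boot == 27
        assert ci.point_estimate == pytest.approx(point, abs=1e-12)
        assert (ci.lower, ci.upper) == pytest.approx((lo, hi), abs=1e-12)

    def test_interval_contains_point_for_sampled_bootstrap(self, rng):
        scores, truths = self._subjects(rng, n=6, voxels=80)
        ci = bootstrap_auc_ci(scores, truths, n_boot=120, seed=5)
        assert ci.lower <= ci.point_estimate <= ci.upper
        assert ci.n_boot == 120

    def test_diff_of_identical_methods_is_zero(self, rng):
        scores, truths = self._subjects(rng)
        ci = bootstrap_auc_diff_ci(scores, scores, truths, n_boot=50, seed=1)
        assert ci.point_estimate == 0.0
        assert ci.lower == ci.upper == 0.0

    def test_diff_sign_for_dominating_method(self, rng):
        scores_a, truths = self._subjects(rng, n=4, voxels=200, effect=2.5)
        scores_b = [rng.standard_normal(200) for _ in range(4)]
        ci = bootstrap_auc_diff_ci(scores_a, scores_b, truths, n_boot=120, seed=2)
        assert ci.lower > 0

    def test_diff_exhaustive_matches_enumeration_oracle(self, rng):
        scores_a, truths = self._subjects(rng, effect=1.5)
        scores_b = [s + rng.standard_normal(s.size) for s in scores_a]
        ci = bootstrap_auc_diff_ci(scores_a, scores_b, truths, seed=0,
                                   exhaustive=True)
        boot = []
        for pick in itertools.product(range(3), repeat=3):
            y = np.concatenate([truths[i] for i in pick])
            a = concordance_auc(y, np.concatenate([scores_a[i] for i in pick]))
            b = concordance_auc(y, np.concatenate([scores_b[i] for i in pick]))
            boot.append(a - b)
        y = np.concatenate(truths)
        point = (concordance_auc(y, np.concatenate(scores_a))
                 - concordance_auc(y, np.concatenate(scores_b)))
        lo, hi = bc_interval_oracle(boot, point)
        assert (ci.lower, ci.upper) == pytest.approx((lo, hi), abs=1e-12)

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_auc_ci([rng.random(10)], [rng.random(10) < 0.5])


class TestBaseline:
    def test_patient_equal_to_control_mean_gives_zero(self, rng):
        controls = [Volume(rng.standard_normal((5, 5, 5))) for _ in range(5)]
        mean = Volume(np.mean([c.data for c in controls], axis=0))
        tmap = univariate_tmap(mean, controls, _full_mask((5, 5, 5)))
        assert np.allclose(tmap.data, 0.0, atol=1e-10)

    def test_hand_computed_t_value(self):
        shape = (3, 3, 3)
        controls = [Volume(np.full(shape, v)) for v in (1.0, 2.0, 3.0)]
        patient = Volume(np.full(shape, 5.0))
        tmap = univariate_tmap(patient, controls, _full_mask(shape))
        # mean 2, sample SD 1, n = 3: t = 3 / sqrt(1 + 1/3)
        assert np.allclose(tmap.data, 3.0 / np.sqrt(4.0 / 3.0))
        assert tmap.data[0, 0, 0] == pytest.approx(2.598, abs=1e-3)

    def test_zero_variance_voxels_excluded(self, rng):
        shape = (4, 4, 4)
        controls = [Volume(rng.standard_normal(shape)) for _ in range(4)]
        for c in controls:
            c.data[0, 0, 0] = 7.0  # degenerate voxel
        patient = Volume(rng.standard_normal(shape))
        tmap = univariate_tmap(patient, controls, _full_mask(shape))
        assert np.isnan(tmap.data[0, 0, 0])
        assert np.isfinite(tmap.data).sum() == 63

    def test_conjunction_is_pointwise_minimum(self, rng):
        a = Volume(rng.standard_normal((5, 5, 5)))
        b = Volume(rng.standard_normal((5, 5, 5)))
        conj = conjunction_map(a, b)
        assert (conj.data <= a.data + 1e-15).all()
        assert (conj.data <= b.data + 1e-15).all()
        assert np.array_equal(conjunction_map(a, a.copy()).data, a.data)

    def test_conjunction_suprathreshold_is_intersection(self, rng):
        a = Volume(rng.standard_normal((8, 8, 8)))
        b = Volume(rng.standard_normal((8, 8, 8)))
        crit = 0.8
        conj = conjunction_map(a, b)
        assert np.array_equal(conj.data > crit, (a.data > crit) & (b.data > crit))

    def test_mip_projects_maximum(self, rng):
        vol = Volume(rng.standard_normal((6, 7, 8)))
        assert np.array_equal(mip(vol, axis=2), vol.data.max(axis=2))
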