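"""Stepwise-regression + LDA decoding with permutation inference."""

import numpy as np
import pytest

from emosearch.features import N_FEATURES
from emosearch.imagebehavior import quartile_labels
from emosearch.decode import (DecodingConfig, cross_condition_transfer,
                              decode_image_labels, decode_metric,
                              lda_quartile_decode, stepwise_cv_fit,
                              stepwise_select)
from emosearch.synth import (make_feature_behavior_dataset,
                             make_labeled_image_set)

FAST = DecodingConfig(seed=5, n_perm_regression=400, n_perm_decode=400)


class TestStepwiseSelect:
    def test_recovers_noiseless_support(self, rng):
        X = rng.standard_normal((200, N_FEATURES))
        idx = [3, 120, 377]
        y = X[:, idx] @ np.array([2.0, -1.5, 1.0])
        sel = stepwise_select(X, y)
        assert set(idx) <= set(sel)

    def test_respects_max_features(self, rng):
        X = rng.standard_normal((60, N_FEATURES))
        y = rng.standard_normal(60)
        assert len(stepwise_select(X, y, max_features=5)) <= 5


class TestRegressionArm:
    def test_noiseless_linear_target_predicts_near_perfectly(self, rng):
        X = rng.standard_normal((200, N_FEATURES))
        beta = np.zeros(N_FEATURES)
        beta[[10, 40, 300]] = [1.0, -2.0, 0.5]
        res = stepwise_cv_fit(X, X @ beta, FAST)
        assert res.rho > 0.95
        assert res.p_rho < 0.001

    def test_defaults_follow_protocol(self):
        cfg = DecodingConfig()
        assert cfg.n_cv_iterations == 10
        assert cfg.holdout_fraction == pytest.approx(1 / 3)
        assert cfg.n_perm_regression == 1000
        assert cfg.n_perm_decode == 10000
        assert cfg.alpha_joint == 0.001

    def test_constant_target_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            stepwise_cv_fit(rng.standard_normal((50, N_FEATURES)),
                            np.ones(50), FAST)

    def test_null_target_not_significant(self):
        X, y, _ = make_feature_behavior_dataset(150, snr=0.0, seed=8)
        res = decode_metric(X, y, cfg=FAST)
        assert not res.significant
        assert abs(res.rho) < 0.35


class TestDecodingArm:
    def test_separable_quartiles_decoded(self, rng):
        n = 240
        X = rng.standard_normal((n, N_FEATURES)) * 0.05
        q = np.repeat([1, 2, 3, 4], n // 4)
        X[:, 7] = q + rng.normal(0, 0.05, n)
        X[:, 19] = -q + rng.normal(0, 0.05, n)
        sets = [[7, 19]] * 10
        res = lda_quartile_decode(X, q, sets, FAST)
        assert res.frac_correct > 0.9
        assert res.null_decode_mean == pytest.approx(0.25, abs=0.02)
        assert res.p_decode < 0.001

    def test_shuffled_labels_stay_at_chance(self, rng):
        n = 240
        X = rng.standard_normal((n, N_FEATURES))
        q = rng.permutation(np.repeat([1, 2, 3, 4], n // 4))
        res = lda_quartile_decode(X, q, [[0, 1, 2]] * 10, FAST)
        assert abs(res.frac_correct - 0.25) < 0.08
        assert res.null_decode_mean == pytest.approx(0.25, abs=0.02)
        assert not (res.p_decode < 0.001)


class TestDeterminism:
    def test_same_seed_same_result(self):
        X, y, _ = make_feature_behavior_dataset(120, snr=2.0, seed=3)
        a = decode_metric(X, y, cfg=FAST)
        b = decode_metric(X, y, cfg=FAST)
        assert a.rho == b.rho and a.p_rho == b.p_rho
        assert a.frac_correct == b.frac_correct
        assert a.selected_features == b.selected_features
        assert np.array_equal(a.mean_betas, b.mean_betas)


class TestTransfer:
    def fit(self, seed, betas=None, n=250):
        X, y, b = make_feature_behavior_dataset(n, betas=betas, snr=2.0,
                                                seed=seed)
        res = decode_metric(X, y, cfg=FAST)
        return X, y, quartile_labels(y), b, res

    def test_shared_mapping_transfers_both_directions(self):
        Xa, ya, qa, beta, res_a = self.fit(seed=21)
        Xb, yb, qb, _, res_b = self.fit(seed=22, betas=beta)
        ab = cross_condition_transfer(res_a, Xa, qa, Xb, yb, qb, FAST)
        ba = cross_condition_transfer(res_b, Xb, qb, Xa, ya, qa, FAST)
        assert ab.significant and ba.significant

    def test_orthogonal_mapping_stays_within_null(self, rng):
        Xa, ya, qa, beta, res_a = self.fit(seed=23)
        other = np.zeros(N_FEATURES)
        free = np.setdiff1d(np.arange(N_FEATURES), np.nonzero(beta)[0])
        other[rng.choice(free, 5, replace=False)] = rng.normal(0, 1, 5)
        Xb, yb, qb, _, _ = self.fit(seed=24, betas=other)
        res = cross_condition_transfer(res_a, Xa, qa, Xb, yb, qb, FAST)
        assert not res.significant
        assert abs(res.rho) < 0.15
        assert abs(res.frac_correct - 0.25) < 0.07

    def test_partial_overlap_sits_between_extremes(self):
        Xa, ya, qa, beta, res_a = self.fit(seed=25)
        rng = np.random.default_rng(99)
        mixed = 0.5 * beta
        free = np.setdiff1d(np.arange(N_FEATURES), np.nonzero(beta)[0])
        mixed[rng.choice(free, 5, replace=False)] = rng.normal(
            0, np.abs(beta).max() / 2, 5)
        Xs, ys, qs, _, _ = self.fit(seed=26, betas=beta)
        Xm, ym, qm, _, _ = self.fit(seed=26, betas=mixed)
        rho_shared = cross_condition_transfer(res_a, Xa, qa, Xs, ys, qs,
                                              FAST).rho
        rho_mixed = cross_condition_transfer(res_a, Xa, qa, Xm, ym, qm,
                                             FAST).rho
        assert 0 < rho_mixed < rho_shared

    def test_no_stable_feature_skips_classification(self, rng):
        from emosearch.decode import DecodingResult

        res_a = DecodingResult(mean_betas=np.zeros(N_FEATURES),
                               mean_intercept=0.0,
                               selected_features=[[1], [2], [3]])
        X = rng.standard_normal((40, N_FEATURES))
        y = rng.standard_normal(40)
        q = quartile_labels(y)
        res = cross_condition_transfer(res_a, X, q, X, y, q, FAST)
        assert res.frac_correct is None
        assert any("skipped" in f for f in res.flags)


class TestLabelDecoding:
    def test_planted_signatures_decoded_across_groups(self):
        X, labels, groups = make_labeled_image_set(20, n_classes=8,
                                                   signature_scale=1.0,
                                                   seed=4)
        res = decode_image_labels(X, labels, groups, FAST)
        assert res.frac_correct > 3 * 0.125
        assert res.null_decode_mean == pytest.approx(0.125, abs=0.01)
        assert res.p_decode < 0.001

    def test_no_signature_stays_at_chance(self):
        X, labels, groups = make_labeled_image_set(20, n_classes=8,
                                                   signature_scale=0.0,
                                                   seed=6)
        res = decode_image_labels(X, labels, groups, FAST)
        assert abs(res.frac_correct - 0.125) < 0.06
        assert not (res.p_decode < 0.001)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError, match="two groups"):
            decode_image_labels(rng.standard_normal((20, N_FEATURES)),
                                np.repeat([0, 1], 10), np.zeros(20), FAST)
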