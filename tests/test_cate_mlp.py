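"""Multi-headed MLP: loss, training loop, ensembles, search, transfer."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from msenrich import apply_exclusions, fit_transform
from msenrich.cate_mlp import (
    EnsembleModel,
    HyperParams,
    MultiHeadMLP,
    apply_one_sd_rule,
    compute_loss_weights,
    cross_validated_ensemble,
    pretrain_and_finetune,
    random_search_select,
    train_fold,
    weighted_factual_loss,
)
from msenrich.exceptions import ParameterError, ValidationError
from msenrich.outcome_labels import label_dataset
from msenrich.synthetic_trials import generate_dataset, ppms_config, strong_linear_cate

ARMS2 = ("treatment", "placebo")


def _toy_data(n=240, n_features=6, seed=0, arms=ARMS2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    alloc = np.array(arms)[rng.integers(0, len(arms), n)]
    effects = {arm: 0.2 * i for i, arm in enumerate(arms)}
    y = X[:, 0] * 0.5 + np.array([effects[a] for a in alloc]) + rng.normal(0, 0.1, n)
    return X, y, alloc


class TestWeightedLoss:
    def test_equal_arm_sizes_reduce_to_plain_mse(self):
        preds = np.array([[1.0, 9.0], [9.0, 2.0], [3.0, 9.0], [9.0, 4.0]])
        y = np.array([0.0, 1.0, 2.0, 3.0])
        alloc = np.array(["a", "b", "a", "b"])
        w = compute_loss_weights(alloc, ("a", "b"))
        assert np.all(w == 1.0)
        loss = weighted_factual_loss(preds, y, alloc, w, arm_ids=("a", "b"))
        assert loss == pytest.approx(np.mean([1.0, 1.0, 1.0, 1.0]))

    def test_hand_arithmetic_with_imbalanced_arms(self):
        # n_s=3, m=2, arm sizes (2,1): weights 0.75 and 1.5; unit squared errors
        preds = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 3.0]])
        y = np.array([0.0, 1.0, 2.0])
        alloc = np.array(["a", "a", "b"])
        w = compute_loss_weights(alloc, ("a", "b"))
        assert list(w) == [0.75, 1.5]
        loss = weighted_factual_loss(preds, y, alloc, w, arm_ids=("a", "b"))
        assert loss == pytest.approx((0.75 + 0.75 + 1.5) / 3)
        assert loss == pytest.approx(1.0)

    def test_perfect_predictions_zero_loss(self):
        preds = np.array([[0.5, 9.0], [9.0, 1.5]])
        y = np.array([0.5, 1.5])
        alloc = np.array(["a", "b"])
        w = compute_loss_weights(alloc, ("a", "b"))
        assert weighted_factual_loss(preds, y, alloc, w, arm_ids=("a", "b")) == 0.0

    def test_unknown_allocation_rejected(self):
        with pytest.raises(ValidationError):
            weighted_factual_loss(
                np.zeros((1, 2)), np.zeros(1), np.array(["c"]), np.ones(2), arm_ids=("a", "b")
            )

    def test_size_weighted_mean_of_weights_is_one(self):
        rng = np.random.default_rng(13)
        alloc = np.array(["a", "b", "c"])[rng.integers(0, 3, 100)]
        w = compute_loss_weights(alloc, ("a", "b", "c"))
        per_patient = np.array([w[("a", "b", "c").index(a)] for a in alloc])
        assert per_patient.mean() == pytest.approx(1.0, abs=1e-12)


class TestTrainFold:
    def test_determinism_bit_identical(self):
        X, y, alloc = _toy_data()
        hp = HyperParams(hidden_width=16, max_epochs=8, seed=42)
        runs = []
        for _ in range(2):
            model, hist = train_fold(
                X[:200], y[:200], alloc[:200], X[200:], y[200:], alloc[200:], hp, ARMS2
            )
            runs.append((model.predict(X), hist))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_history_bounded_and_snapshot_is_argmin(self):
        X, y, alloc = _toy_data(seed=1)
        hp = HyperParams(hidden_width=16, max_epochs=30, seed=0)
        model, hist = train_fold(
            X[:200], y[:200], alloc[:200], X[200:], y[200:], alloc[200:], hp, ARMS2
        )
        assert len(hist["val_mse"]) <= 100
        best = int(np.argmin(hist["val_mse"]))
        assert hist["best_epoch"] == best + 1
        # re-evaluating the returned snapshot reproduces the recorded minimum
        arm_pos = {a: i for i, a in enumerate(ARMS2)}
        idx = np.array([arm_pos[a] for a in alloc[200:]])
        preds = model.predict(X[200:])
        mse = np.mean((preds[np.arange(idx.size), idx] - y[200:]) ** 2)
        assert mse == pytest.approx(hist["val_mse"][best], abs=1e-12)

    def test_max_norm_constraint_holds(self):
        X, y, alloc = _toy_data(seed=2)
        hp = HyperParams(hidden_width=16, max_epochs=10, max_norm=0.5, seed=0)
        model, _ = train_fold(
            X[:200], y[:200], alloc[:200], X[200:], y[200:], alloc[200:], hp, ARMS2
        )
        for key, p in model.params.items():
            if p.ndim == 2:
                assert np.all(np.linalg.norm(p, axis=0) <= hp.max_norm + 1e-9)

    def test_empty_split_rejected(self):
        X, y, alloc = _toy_data()
        hp = HyperParams()
        with pytest.raises(ValidationError):
            train_fold(X[:0], y[:0], alloc[:0], X, y, alloc, hp, ARMS2)


class TestPredictCate:
    def _constant_model(self, mu_t, mu_c):
        model = MultiHeadMLP(4, ARMS2, hidden_width=8, seed=0)
        model.params["trunk_W"][:] = 0.0
        for arm, mu in zip(ARMS2, (mu_t, mu_c)):
            model.params[f"{arm}_W1"][:] = 0.0
            model.params[f"{arm}_b1"][:] = 0.0
            model.params[f"{arm}_W2"][:] = 0.0
            model.params[f"{arm}_b2"][:] = mu
        return model

    def test_sign_flip_reports_benefit_positive(self):
        # treatment slope 0.1/yr, placebo 0.3/yr -> reported CATE +0.2
        model = self._constant_model(0.1, 0.3)
        X = np.zeros((3, 4))
        assert model.predict_cate(X, "treatment", "placebo") == pytest.approx(0.2)

    def test_identical_heads_zero_cate(self):
        model = self._constant_model(0.3, 0.3)
        assert model.predict_cate(np.zeros((2, 4)), "treatment", "placebo") == pytest.approx(0.0)

    def test_antisymmetry(self):
        model = MultiHeadMLP(4, ARMS2, hidden_width=8, seed=3)
        X = np.random.default_rng(4).normal(size=(10, 4))
        fwd = model.predict_cate(X, "treatment", "placebo")
        rev = model.predict_cate(X, "placebo", "treatment")
        assert np.array_equal(fwd, -rev)

    def test_unregistered_arm_rejected(self):
        model = MultiHeadMLP(4, ARMS2, hidden_width=8, seed=0)
        with pytest.raises(ValidationError):
            model.predict_cate(np.zeros((1, 4)), "treatment", "nope")


class TestEnsemble:
    def test_prediction_is_mean_of_members(self):
        members = [MultiHeadMLP(4, ARMS2, 8, seed=s) for s in range(4)]
        ens = EnsembleModel(members=members, arm_ids=ARMS2)
        X = np.random.default_rng(5).normal(size=(7, 4))
        expected = np.mean([m.predict(X) for m in members], axis=0)
        assert np.array_equal(ens.predict(X), expected)

    def test_crogged_mse_equals_manual_pooling(self):
        X, y, alloc = _toy_data(seed=6)
        hp = HyperParams(hidden_width=16, max_epochs=5, seed=0)
        _, metrics = cross_validated_ensemble(X, y, alloc, hp, k=4)
        oof = metrics["oof_predictions"]
        assert np.all(np.isfinite(oof))
        assert metrics["crogged_mse"] == pytest.approx(np.mean((oof - y) ** 2), abs=1e-12)

    def test_serialization_round_trip(self):
        X, y, alloc = _toy_data(seed=7)
        hp = HyperParams(hidden_width=16, max_epochs=3, seed=0)
        ens, _ = cross_validated_ensemble(X, y, alloc, hp, k=2)
        restored = EnsembleModel.from_dict(ens.to_dict())
        assert np.array_equal(ens.predict(X), restored.predict(X))


class TestOneSdRule:
    def test_better_ad_within_one_sd_selected(self):
        # A: MSE 1.0, per-fold SD ~0.28, AD 0.01; B: MSE 1.1, AD 0.05 -> B
        idx = apply_one_sd_rule(
            [1.0, 1.1], [[0.8, 1.2], [1.0, 1.2]], [0.01, 0.05]
        )
        assert idx == 1

    def test_ineligible_candidate_excluded(self):
        # B's MSE 1.5 exceeds 1.0 + SD -> A wins despite lower AD
        idx = apply_one_sd_rule(
            [1.0, 1.5], [[0.8, 1.2], [1.4, 1.6]], [0.01, 0.05]
        )
        assert idx == 0

    def test_single_candidate_always_selected(self):
        X, y, alloc = _toy_data(seed=8)
        res = random_search_select(
            X, y, alloc, n_candidates=1, seed=0, k=2,
            base_hp=HyperParams(hidden_width=8, max_epochs=2),
        )
        assert res.selected_index == 0

    def test_no_candidates_rejected(self):
        with pytest.raises(ParameterError):
            random_search_select(np.zeros((4, 2)), np.zeros(4), np.array(["a"] * 4),
                                 n_candidates=0)


class TestTransfer:
    def _small_transfer(self, epochs=4):
        Xr, yr, ar = _toy_data(
            n=300, seed=9, arms=("a1", "a2", "a3", "a4", "placebo")
        )
        Xp, yp, ap = _toy_data(n=200, seed=10)
        hp = HyperParams(hidden_width=16, max_epochs=epochs, seed=1)
        return pretrain_and_finetune((Xr, yr, ar), (Xp, yp, ap), hp, hp, k=2)

    def test_trunk_bit_identical_after_finetuning(self):
        res = self._small_transfer()
        for pre, fine in zip(res.pretrained.members, res.ensemble.members):
            assert np.array_equal(pre.params["trunk_W"], fine.params["trunk_W"])
            assert np.array_equal(pre.params["trunk_b"], fine.params["trunk_b"])
            assert fine.trunk_frozen

    def test_head_counts_match_phases(self):
        res = self._small_transfer()
        assert all(len(m.arm_ids) == 5 for m in res.pretrained.members)
        assert all(len(m.arm_ids) == 2 for m in res.ensemble.members)

    def test_head_parameters_train_during_finetuning(self):
        res = self._small_transfer()
        for fold, member in enumerate(res.ensemble.members):
            fresh = MultiHeadMLP(
                member.n_features, member.arm_ids, member.hidden_width, seed=1 + fold
            )
            assert not np.array_equal(
                member.params["treatment_W2"], fresh.params["treatment_W2"]
            )

    def test_width_mismatch_rejected(self):
        Xr, yr, ar = _toy_data(n=60, seed=11)
        with pytest.raises(ParameterError):
            pretrain_and_finetune(
                (Xr, yr, ar), (Xr, yr, ar),
                HyperParams(hidden_width=8), HyperParams(hidden_width=16),
            )


class TestRecovery:
    def test_synthetic_cate_recovery_beats_random_ranking(self):
        """On a strongly heterogeneous synthetic cohort (n=2000) the fitted
        ensemble ranks true effects well and its AD_wabc beats random."""
        from msenrich.survival_eval import ad_curve, ad_wabc

        cfg = ppms_config(n=2000, cate=strong_linear_cate(), seed=7)
        ds, truth = generate_dataset(cfg)
        ds, _ = apply_exclusions(ds)
        _, matrix = fit_transform(ds, reference_trial_id="TRIAL_A")
        lab = label_dataset(ds)
        X = matrix.to_numpy()
        y = lab.loc[matrix.index, "slope"].to_numpy()
        alloc = np.array([p.arm_id for p in ds.patients])
        treated = alloc == "treatment"
        times = lab["ttcdp24_years"].to_numpy()
        events = lab["event"].to_numpy(dtype=bool)

        ens, metrics = cross_validated_ensemble(
            X, y, alloc, HyperParams(seed=7), k=4,
            survival=(times, events, treated), cate_arms=ARMS2,
        )
        tau = truth.loc[matrix.index, "true_cate"].to_numpy()
        pred = ens.predict_cate(X, "treatment", "placebo")
        assert spearmanr(pred, tau).statistic > 0.5

        rng = np.random.default_rng(7)
        ad_model = metrics["crogged_ad_wabc"]
        ad_random = ad_wabc(ad_curve(rng.permutation(pred), times, events, treated))
        assert ad_model > ad_random
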