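"""Classifier architecture, training behavior, and evaluation metrics."""

import numpy as np
import pytest

import hgtsite as h
from hgtsite.model import ModelConfigError

from tests.oracles import ap_direct, auc_pair_counting, delong_permutation_p


def _toy_separable(n=120):
    """Linearly separable toy windows: positives all-A, negatives all-C."""
    samples = [
        h.LabeledSample(h.DnaSequence(f"p{i}", "A" * 100), 1, "r", 0, "positive")
        for i in range(n // 2)
    ] + [
        h.LabeledSample(h.DnaSequence(f"n{i}", "C" * 100), 0, "r", 0, "negative")
        for i in range(n // 2)
    ]
    return h.SampleSet(samples)


class TestArchitecture:
    def test_block_ablation_parameter_arithmetic(self):
        counts = {k: h.build_model(h.k_block_spec(k)).count_parameters() for k in (1, 2, 3, 4)}
        for k in (2, 3, 4):
            assert counts[k] - counts[k - 1] == 131_840  # one residual block
        assert counts[4] == h.build_model(h.cnn_spec()).count_parameters()

    def test_spec_validation(self):
        with pytest.raises(ModelConfigError):
            h.ModelSpec(n_res_blocks=2)  # four dropout rates for two blocks
        with pytest.raises(ModelConfigError):
            h.ModelSpec(kernel_width=200)
        with pytest.raises(ModelConfigError):
            h.ModelSpec(n_res_blocks=5, dropout_rates=(0.1,) * 5)

    def test_k_block_spec_keeps_final_dropout(self):
        assert h.k_block_spec(1).dropout_rates == (0.5,)
        assert h.k_block_spec(3).dropout_rates == (0.1, 0.25, 0.5)

    def test_save_load_round_trip(self, tiny_spec, tmp_path):
        model = h.build_model(tiny_spec, seed=0)
        x = h.SampleSet(_toy_separable(8).samples).one_hot()
        expected = model.predict_proba(x)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = h.HgtClassifier.load(path)
        np.testing.assert_allclose(back.predict_proba(x), expected, rtol=0, atol=0)
        assert back.spec == model.spec


class TestPredict:
    def test_outputs_in_open_unit_interval(self, tiny_spec):
        model = h.build_model(tiny_spec, seed=1)
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(16)]
        preds = h.predict(model, seqs)
        assert ((preds > 0) & (preds < 1)).all()

    def test_duplicated_rows_identical(self, tiny_spec):
        model = h.build_model(tiny_spec, seed=2)
        seq = "ACGT" * 25
        preds = h.predict(model, [seq, seq, seq])
        assert preds[0] == preds[1] == preds[2]

    def test_batch_size_invariance(self, tiny_spec):
        model = h.build_model(tiny_spec, seed=3)
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(300)]
        a = h.predict(model, seqs, batch_size=1)
        b = h.predict(model, seqs, batch_size=256)
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_wrong_length_names_record(self, tiny_spec):
        model = h.build_model(tiny_spec, seed=4)
        with pytest.raises(ValueError, match="bad_record"):
            h.predict(model, [h.DnaSequence("bad_record", "ACGT")])


class TestTraining:
    def test_toy_set_loss_decreases(self, tiny_spec):
        model = h.build_model(tiny_spec, seed=5)
        toy = _toy_separable()
        h.train(model, toy, toy, h.TrainConfig(epochs=5, learning_rate=0.01, seed=5))
        hist = model.history["train_loss"]
        assert len(hist) == 5
        assert hist[-1] < hist[0]

    def test_toy_set_converges_with_augmentation(self, tiny_spec):
        model = h.build_model(tiny_spec, seed=6)
        toy = _toy_separable()
        cfg = h.TrainConfig(epochs=5, learning_rate=0.01, seed=6, augment=True, max_changes=5)
        h.train(model, toy, None, cfg)
        assert model.history["train_loss"][-1] < model.history["train_loss"][0]

    def test_zero_epochs_is_a_no_op(self, tiny_spec):
        model = h.build_model(tiny_spec, seed=7)
        h.train(model, _toy_separable(), None, h.TrainConfig(epochs=0, seed=0))
        assert model.history == {"train_loss": [], "val_loss": []}

    def test_deterministic_under_seed(self, tiny_spec):
        toy = _toy_separable(24)
        outs = []
        for _ in range(2):
            model = h.build_model(tiny_spec, seed=8)
            h.train(model, toy, None, h.TrainConfig(epochs=2, learning_rate=0.01, seed=9))
            outs.append(h.predict(model, toy))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_config_validation(self):
        with pytest.raises(ModelConfigError):
            h.TrainConfig(batch_size=0)
        with pytest.raises(ModelConfigError):
            h.TrainConfig(learning_rate=0)


class TestEvaluate:
    def test_perfect_ranking(self):
        rep = h.evaluate([0.2, 0.8], [0, 1])
        assert rep.auc == 1.0 and rep.ap == 1.0

    def test_all_ties_give_half_auc(self):
        rep = h.evaluate([0.5] * 10, [0, 1] * 5)
        assert rep.auc == 0.5

    def test_matches_pair_counting_and_direct_ap_oracles(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            preds = np.round(rng.random(n), 2)  # rounding forces some ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            rep = h.evaluate(preds, labels)
            assert rep.auc == pytest.approx(auc_pair_counting(preds, labels))
            assert rep.ap == pytest.approx(ap_direct(preds, labels))

    def test_accuracy_threshold(self):
        rep = h.evaluate([0.4, 0.6, 0.6, 0.2], [0, 1, 0, 1], threshold=0.5)
        assert rep.accuracy == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            h.evaluate([0.1, 0.9], [1, 1])


class TestYouden:
    def test_enumerated_example(self):
        assert h.youden_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1]) == 0.6

    def test_separated_data_returns_smallest_positive_prediction(self):
        preds = [0.05, 0.1, 0.62, 0.7, 0.9]
        labels = [0, 0, 1, 1, 1]
        assert h.youden_threshold(preds, labels) == 0.62

    def test_inverted_labels_warn(self):
        with pytest.warns(UserWarning, match="J is ≤ 0"):
            h.youden_threshold([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        preds = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        best = max(
            np.unique(preds),
            key=lambda t: (
                ((preds >= t) & (labels == 1)).sum() / labels.sum()
                + ((preds < t) & (labels == 0)).sum() / (labels == 0).sum(),
                -t,
            ),
        )
        assert h.youden_threshold(preds, labels) == pytest.approx(best)


class TestDelong:
    def test_identical_predictions_give_p_one(self):
        preds = np.linspace(0.1, 0.9, 20)
        labels = (preds > 0.4).astype(int)
        with pytest.warns(UserWarning, match="zero variance"):
            _, _, p = h.delong_test(preds, preds, labels)
        assert p == 1.0

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(4)
        labels = np.array([0, 1] * 10)
        signal = labels + rng.normal(0, 1.2, size=20)
        preds_a = 1 / (1 + np.exp(-signal))
        preds_b = 1 / (1 + np.exp(-(labels + rng.normal(0, 2.5, size=20))))
        _, _, p = h.delong_test(preds_a, preds_b, labels)
        p_perm = delong_permutation_p(preds_a, preds_b, labels, n_reps=10_000, seed=0)
        assert abs(p - p_perm) < 0.1

    def test_power_against_random_predictions(self):
        rng = np.random.default_rng(5)
        labels = np.array([0, 1] * 100)
        strong = labels * 0.8 + rng.normal(0, 0.05, 200)
        random_preds = rng.random(200)
        auc_a, auc_b, p = h.delong_test(strong, random_preds, labels)
        assert auc_a > 0.95 and p < 0.05

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        labels = np.array([0, 1] * 15)
        a, b = rng.random(30), rng.random(30)
        auc_a, auc_b, p_ab = h.delong_test(a, b, labels)
        auc_b2, auc_a2, p_ba = h.delong_test(b, a, labels)
        assert (auc_a, auc_b, p_ab) == (auc_a2, auc_b2, p_ba)


class TestGroupwiseAuc:
    def test_identical_groups_identical_auc(self):
        preds = np.array([0.1, 0.9, 0.1, 0.9])
        labels = np.array([0, 1, 0, 1])
        groups = np.array(["a", "a", "b", "b"])
        table = h.groupwise_auc(preds, labels, groups)
        assert table["auc"].nunique() == 1

    def test_consistency_with_evaluate(self):
        rng = np.random.default_rng(7)
        preds = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        labels[:4] = [0, 1, 0, 1]
        groups = np.repeat(["x", "y"], 30)
        table = h.groupwise_auc(preds, labels, groups).set_index("group")
        for g in ("x", "y"):
            mask = groups == g
            assert table.loc[g, "auc"] == pytest.approx(h.evaluate(preds[mask], labels[mask]).auc)

    def test_single_class_group_omitted(self):
        with pytest.warns(UserWarning, match="single class"):
            table = h.groupwise_auc(
                [0.1, 0.9, 0.5], [0, 1, 1], np.array(["a", "a", "b"])
            )
        assert list(table["group"]) == ["a"]

    def test_corruption_orders_group_aucs(self, trained_small_model):
        """A species whose planted signatures are heavily corrupted should be
        harder to recognize than a clean one."""
        model, _, _, _, _ = trained_small_model
        rows = {}
        for species, corruption, seed in (("clean", 0.02, 21), ("noisy", 0.45, 22)):
            cfg = h.SimulationConfig(
                n_refs=1, ref_length=60_000, sites_per_ref=100, site_spacing=150,
                arm_length_range=(8, 8), corruption=corruption, seed=seed,
            )
            sample_set, _, _ = h.simulate_labeled_set(cfg, 100, 100)
            preds = h.predict(model, sample_set)
            rows[species] = h.evaluate(preds, sample_set.labels()).auc
        assert rows["clean"] > rows["noisy"]
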