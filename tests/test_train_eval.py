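"""Splitting, loss properties, the training loop, and evaluation reports."""

import numpy as np
import pytest

from spineseg import nn
from spineseg.chaspprau import SegModelConfig, build_seg_model
from spineseg.nn import Tensor
from spineseg.train_eval import (TrainConfig, evaluate, segmentation_loss,
                                 soft_dice, split_dataset, train,
                                 binary_dice_score, write_history)


class TestSplitDataset:
    def test_80_20_sizes(self):
        train_l, test_l = split_dataset(list(range(10)), 0.8, seed=0)
        assert len(train_l) == 8 and len(test_l) == 2

    def test_deterministic(self):
        a = split_dataset(list(range(20)), 0.8, seed=5)
        b = split_dataset(list(range(20)), 0.8, seed=5)
        assert a == b

    def test_partition(self):
        items = list(range(13))
        train_l, test_l = split_dataset(items, 0.8, seed=2)
        assert set(train_l) | set(test_l) == set(items)
        assert not set(train_l) & set(test_l)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1], 0.8, seed=0)

    def test_neither_side_empty_even_at_extremes(self):
        train_l, test_l = split_dataset(list(range(3)), 0.95, seed=0)
        assert len(train_l) >= 1 and len(test_l) >= 1


class TestSegmentationLoss:
    def test_one_hot_match_is_near_zero(self):
        truth = np.array([[[0, 1], [1, 0]]])
        logits = np.zeros((1, 2, 2, 2), np.float32)
        # large margins toward the true class
        logits[0, 0] = np.where(truth[0] == 0, 50.0, -50.0)
        logits[0, 1] = np.where(truth[0] == 1, 50.0, -50.0)
        loss = segmentation_loss(Tensor(logits), truth)
        assert float(loss.data) < 1e-6

    def test_uniform_prediction_cross_entropy_is_ln2(self):
        truth = np.zeros((1, 4, 4), np.int64)
        logits = Tensor(np.zeros((1, 2, 4, 4), np.float32))
        loss = segmentation_loss(logits, truth, weights=(0.0, 1.0))
        assert float(loss.data) == pytest.approx(np.log(2), rel=1e-5)

    def test_loss_nonnegative(self, rng):
        logits = Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        truth = rng.integers(0, 3, size=(2, 8, 8))
        assert float(segmentation_loss(logits, truth).data) >= 0.0

    def test_perfect_soft_dice_is_one(self):
        truth = np.array([[[0, 1], [1, 0]]])
        probs = np.zeros((1, 2, 2, 2), np.float32)
        probs[0, 0] = truth[0] == 0
        probs[0, 1] = truth[0] == 1
        assert float(soft_dice(Tensor(probs), truth).data) == pytest.approx(
            1.0, abs=1e-6)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            segmentation_loss(Tensor(np.zeros((1, 2, 4, 4), np.float32)),
                              np.zeros((1, 5, 5), np.int64))

    def test_loss_decreases_when_overfitting_one_sample(self, rng):
        model = build_seg_model(SegModelConfig(base_width=4, depth=1, seed=3,
                                               dropout=0.0))
        x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
        t = (rng.random((1, 16, 16)) > 0.7).astype(np.int64)
        opt = nn.Adam(model.parameters(), lr=1e-3)
        losses = []
        for _ in range(50):
            loss = segmentation_loss(model(Tensor(x)), t)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        # overall decreasing trend: last quartile well below the first
        assert np.mean(losses[-12:]) < 0.8 * np.mean(losses[:12])


def _tiny_items(rng, n=6):
    items = []
    for _ in range(n):
        x = rng.normal(size=(1, 16, 16)).astype(np.float32)
        t = np.zeros((16, 16), np.int64)
        t[4:12, 4:12] = 1
        x[0, 4:12, 4:12] += 3.0
        items.append((x, t))
    return items


def _forward(model, xs):
    return model(Tensor(xs))


def _predict(model):
    def f(x):
        with nn.no_grad():
            return model(Tensor(x[None])).data[0].argmax(axis=0)
    return f


class TestTrainLoop:
    def test_history_length_and_determinism(self, rng):
        items = _tiny_items(rng)
        cfg = TrainConfig(epochs=3, batch_size=2, seed=9)

        def run():
            model = build_seg_model(SegModelConfig(base_width=4, depth=1,
                                                   seed=5))
            hist, best = train(model, items[:4], items[4:], cfg,
                               forward=_forward, predict=_predict(model),
                               score=binary_dice_score)
            return hist, best

        h1, b1 = run()
        h2, b2 = run()
        assert len(h1) == 3
        assert [r.train_loss for r in h1] == [r.train_loss for r in h2]
        assert b1["dice"] == b2["dice"]

    def test_empty_sets_rejected(self, rng):
        model = build_seg_model(SegModelConfig(base_width=4, depth=1))
        with pytest.raises(ValueError):
            train(model, [], _tiny_items(rng), TrainConfig(epochs=1),
                  forward=_forward, predict=_predict(model))

    def test_history_written_as_jsonl(self, rng, tmp_path):
        items = _tiny_items(rng)
        cfg = TrainConfig(epochs=2, batch_size=2, seed=1)
        model = build_seg_model(SegModelConfig(base_width=4, depth=1, seed=5))
        hist, _ = train(model, items[:4], items[4:], cfg, forward=_forward,
                        predict=_predict(model), score=binary_dice_score)
        write_history(hist, tmp_path / "h.jsonl")
        lines = (tmp_path / "h.jsonl").read_text().strip().splitlines()
        assert len(lines) == 2


class TestEvaluate:
    def test_ground_truth_against_itself_scores_100(self, rng):
        t = rng.integers(0, 3, size=(8, 8, 8))
        result = evaluate(lambda x: x, [(t, t)], task="recog")
        assert result["aggregate"]["dice"] == 1.0
        assert result["aggregate"]["precision"] == 1.0

    def test_aggregate_is_mean_of_rows(self, rng):
        items = [(rng.integers(0, 2, size=(6, 6)),
                  rng.integers(0, 2, size=(6, 6))) for _ in range(3)]
        result = evaluate(lambda x: x, items, task="seg")
        assert result["aggregate"]["dice"] == pytest.approx(
            np.mean([r["dice"] for r in result["rows"]]))

    def test_row_count_matches_test_set(self, rng):
        items = [(np.ones((4, 4), int), np.ones((4, 4), int))
                 for _ in range(5)]
        result = evaluate(lambda x: x, items, task="seg")
        assert len(result["rows"]) == 5

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(lambda x: x, [], task="seg")

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            evaluate(lambda x: x, [(np.zeros((2, 2)), np.zeros((2, 2)))],
                     task="detect")
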