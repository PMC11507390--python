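"""Distillation and expected-gradients attribution."""

import numpy as np
import pytest

from offgru.encoding import GuidePair, encode_batch
from offgru.interpret import (AttributionMap, base_pair_table, distill,
                              expected_gradients, explain_base_pairs,
                              explain_positions, _model_grad)
from offgru.network import ModelConfig, ModelHandle, TrainConfig, train


class LinearSigmoidModel:
    """Planted surrogate: f(x) = sigmoid(<c, x>), exact gradient known."""

    def __init__(self, coef):
        self.coef = np.asarray(coef, dtype=float)

    def f(self, x):
        z = np.tensordot(x, self.coef, axes=([1, 2], [0, 1]))
        return 1.0 / (1.0 + np.exp(-z))

    def grad(self, x):
        p = self.f(x)
        return (p * (1 - p))[:, None, None] * self.coef[None]


def test_constant_model_zero_attribution():
    """A model whose output ignores the input attributes ~0 everywhere."""
    rng = np.random.default_rng(0)
    x = rng.random((4, 24, 7))
    bg = rng.random((8, 24, 7))
    attr = expected_gradients(lambda b: np.zeros_like(b), x, bg, n_steps=8)
    assert np.all(attr == 0)


def test_planted_linear_surrogate_recovery():
    """Expected gradients recover planted per-position coefficients: for a
    linear-in-input model the attribution is exactly (x - E[b]) * slope
    averaged over the path, so heavy positions rank on top."""
    rng = np.random.default_rng(1)
    coef = np.zeros((24, 7))
    heavy = [2, 7, 15, 19]
    coef[heavy, 0] = [3.0, 4.0, 5.0, 6.0]
    model = LinearSigmoidModel(coef)
    x = (rng.random((40, 24, 7)) < 0.3).astype(float)
    bg = (rng.random((30, 24, 7)) < 0.3).astype(float)
    attr = expected_gradients(model.grad, x, bg, n_steps=32)
    importance = np.abs(attr.mean(axis=0)).sum(axis=1)
    top = set(np.argsort(importance)[-4:])
    assert top == set(heavy)


def test_expected_gradients_completeness():
    """Per-sample attributions sum to f(x) - E_b[f(b)] (completeness)."""
    rng = np.random.default_rng(2)
    coef = rng.normal(scale=0.5, size=(24, 7))
    model = LinearSigmoidModel(coef)
    x = rng.random((6, 24, 7))
    bg = rng.random((20, 24, 7))
    attr = expected_gradients(model.grad, x, bg, n_steps=64)
    totals = attr.sum(axis=(1, 2))
    expected = model.f(x) - model.f(bg).mean()
    assert np.allclose(totals, expected, atol=1e-2)


def test_network_completeness(trained_tiny):
    """Completeness also holds through the real network's input gradient."""
    model, X, _ = trained_tiny
    rng = np.random.default_rng(3)
    x = X[rng.choice(len(X), 5, replace=False)]
    bg = X[rng.choice(len(X), 25, replace=False)]
    attr = expected_gradients(_model_grad(model), x, bg, n_steps=48)
    expected = model.predict_scores(x) - model.predict_scores(bg).mean()
    assert np.allclose(attr.sum(axis=(1, 2)), expected, atol=1e-2)


def test_attribution_seeded_determinism(trained_tiny, small_dataset):
    model, _, _ = trained_tiny
    pairs, _ = small_dataset
    a = explain_positions(model, pairs[:200], n_background=20, n_steps=8,
                          seed=5)
    b = explain_positions(model, pairs[:200], n_background=20, n_steps=8,
                          seed=5)
    assert np.array_equal(a.values, b.values)
    assert a.standardized


def test_standardize_idempotent_and_order_preserving():
    rng = np.random.default_rng(4)
    amap = AttributionMap(rng.normal(size=(24, 7)), tuple("ABCDEFG"), False)
    z1 = amap.standardize()
    z2 = z1.standardize()
    assert np.allclose(z1.values, z2.values, atol=1e-12)
    assert z1.values.mean() == pytest.approx(0, abs=1e-12)
    assert z1.values.std() == pytest.approx(1)
    order = np.argsort(amap.values.ravel())
    assert np.array_equal(order, np.argsort(z1.values.ravel()))


def test_explain_requires_positives(trained_tiny):
    model, _, _ = trained_tiny
    guide = "A" * 20 + "TGG"
    negatives = [GuidePair(guide, guide, 0, "g") for _ in range(5)]
    with pytest.raises(ValueError, match="positive"):
        explain_positions(model, negatives, n_background=2, n_steps=2)


def test_absent_base_pairs_get_zero_attribution(small_dataset):
    """Channels for base pairs that never occur in the explained records
    receive exactly zero raw attribution (input equals baseline there)."""
    guide = "A" * 20 + "TGG"
    pairs = [GuidePair(guide, guide, i % 2, "g") for i in range(20)]
    student = ModelHandle(ModelConfig.student(), seed=0)
    rng = np.random.default_rng(0)
    X = encode_batch(pairs, "16ch")
    attr = expected_gradients(_model_grad(student), X[:4], X[4:10], n_steps=4)
    present = X.max(axis=0).astype(bool)
    assert np.all(attr[:, ~present] == 0)


def test_distill_rejects_indels_and_wrong_teacher(indel_dataset,
                                                 small_dataset):
    pairs_indel, _ = indel_dataset
    teacher = ModelHandle(ModelConfig(), seed=0)
    with pytest.raises(ValueError, match="mismatch-only"):
        distill(teacher, pairs_indel)
    pairs, _ = small_dataset
    not_teacher = ModelHandle(ModelConfig.student(), seed=0)
    with pytest.raises(ValueError, match="7-channel"):
        distill(not_teacher, pairs[:50])


def test_distill_alpha_one_equals_plain_student(small_dataset):
    """With alpha=1 the teacher cannot influence training: the distilled
    student equals a plain student trained from the same seed."""
    pairs, _ = small_dataset
    subset = pairs[:300]
    if not any(p.label for p in subset):
        subset = pairs
    teacher = ModelHandle(ModelConfig(), seed=1)  # untrained is fine here
    cfg = TrainConfig(epochs=2, batch_size=64)
    student = distill(teacher, subset, alpha=1.0, seed=4, train_cfg=cfg)

    plain = ModelHandle(ModelConfig.student(), seed=4)
    X16 = encode_batch(subset, "16ch")
    y = np.array([p.label for p in subset])
    train(plain, X16, y, cfg)
    assert np.array_equal(student.predict(X16), plain.predict(X16))


def test_planted_base_pair_cell_ranks_first():
    """When one specific mismatch at one position drives the labels, that
    (pair, position) cell tops the student's attribution table."""
    rng = np.random.default_rng(6)
    guide = "ACGTACGTACGTACGTACGTTGG"
    pairs = []
    for i in range(400):
        target = list(guide)
        if rng.random() < 0.5:  # plant: C->A mismatch at position 18
            target[17] = "A"
            label = 1
        else:
            # a random decoy mismatch elsewhere
            pos = int(rng.integers(0, 16))
            target[pos] = rng.choice([b for b in "ACGT" if b != guide[pos]])
            label = 0
        pairs.append(GuidePair(guide, "".join(target), label, "g"))
    assert guide[17] == "C"

    X16 = encode_batch(pairs, "16ch")
    y = np.array([p.label for p in pairs])
    student = ModelHandle(ModelConfig.student(), seed=0)
    train(student, X16, y, TrainConfig(epochs=12, batch_size=128))
    amap = explain_base_pairs(student, pairs, n_background=40, n_steps=12,
                              seed=0)
    table = base_pair_table(amap)
    top = table.loc[table["value"].idxmax()]
    assert top["label"] == "C-A:18"


def test_base_pair_table_format(small_dataset, trained_tiny):
    rng = np.random.default_rng(7)
    amap = AttributionMap(rng.normal(size=(24, 16)),
                          tuple(g + d for g in "ATGC" for d in "ATCG"), True)
    table = base_pair_table(amap)
    assert len(table) <= 24 * 16
    for _, row in table.sample(10, random_state=0).iterrows():
        pair, pos = row["label"].split(":")
        g, d = pair.split("-")
        assert g in "ACGT" and d in "ACGT" and 1 <= int(pos) <= 20
        assert row["value"] == amap.values[int(pos) - 1,
                                           amap.channel_names.index(g + d)]
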