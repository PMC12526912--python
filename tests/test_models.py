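"""Architecture parameter accounting, backend gradients, training, metrics."""

import numpy as np
import pytest

from ecgbeat import nn
from ecgbeat.models import (
    AAMI_CLASSES,
    ArchitectureSpec,
    ModelError,
    TrainConfig,
    build_bilstm,
    build_lstm_fcn,
    build_lstm_sequential,
    evaluate,
    instantiate,
    layer_parameter_counts,
    load_model,
    parameter_count,
    report_from_predictions,
    save_model,
    train,
)
from ecgbeat.synthdata import make_separable_dataset


def labelled(X, y):
    return X, np.array([AAMI_CLASSES[i] for i in y])


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

def test_lstm_sequential_layer_counts():
    counts = [c for c in layer_parameter_counts(build_lstm_sequential()) if c]
    assert counts == [264192, 32896, 645]


def test_lstm_sequential_512_variant():
    spec = build_lstm_sequential(lstm_units=512)
    counts = [c for c in layer_parameter_counts(spec) if c]
    assert counts[0] == 4 * (512 * 513 + 512)
    assert parameter_count(spec) == instantiate(spec).count_params()


def test_bilstm_layer_counts():
    counts = [c for c in layer_parameter_counts(build_bilstm()) if c]
    assert counts == [528384, 131328, 1285]


def test_lstm_fcn_layer_counts():
    counts = [c for c in layer_parameter_counts(build_lstm_fcn()) if c]
    # table order: conv1, bn1, conv2, bn2, conv3, bn3, lstm, dense
    assert counts == [320, 102528, 512, 164096, 1024, 98432, 512, 685]


def test_smallest_lstm_units():
    assert [c for c in layer_parameter_counts(build_lstm_sequential(lstm_units=1)) if c][0] == 12
    assert [c for c in layer_parameter_counts(build_bilstm(lstm_units=1)) if c][0] == 24
    assert [c for c in layer_parameter_counts(build_lstm_fcn(num_cells=1)) if c][0] == 12


def test_empty_spec_counts_zero():
    spec = ArchitectureSpec("empty", 9, layers=())
    assert parameter_count(spec) == 0


@pytest.mark.parametrize("spec", [
    build_lstm_sequential(), build_lstm_sequential(lstm_units=512),
    build_bilstm(), build_bilstm(lstm_units=512), build_lstm_fcn(),
], ids=["lstm256", "lstm512", "bilstm256", "bilstm512", "lstm_fcn"])
def test_backend_matches_closed_form(spec):
    assert instantiate(spec).count_params() == parameter_count(spec)


# ---------------------------------------------------------------------------
# backend correctness
# ---------------------------------------------------------------------------

def numeric_gradient(net, X, Y, param, eps=1e-6):
    g = np.zeros_like(param)
    flat = param.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        lp, _ = nn.softmax_cross_entropy(net.forward(X, training=False), Y)
        flat[i] = orig - eps
        lm, _ = nn.softmax_cross_entropy(net.forward(X, training=False), Y)
        flat[i] = orig
        gflat[i] = (lp - lm) / (2 * eps)
    return g


def test_chain_backprop_matches_numeric_gradient():
    rng = np.random.default_rng(0)
    net = nn.Chain([
        nn.LSTM(1, 3, rng),
        nn.Dense(3, 4, "tanh", rng),
        nn.Dense(4, 5, "softmax", rng),
    ])
    X = rng.standard_normal((6, 7, 1))
    Y = np.eye(5)[rng.integers(0, 5, 6)]
    logits = net.forward(X, training=False)
    _, dlogits = nn.softmax_cross_entropy(logits, Y)
    net.backward(dlogits)
    for layer in net.layers:
        for p, g in zip(layer.params, layer.grads):
            assert np.max(np.abs(g - numeric_gradient(net, X, Y, p))) < 1e-6


def test_two_branch_backprop_matches_numeric_gradient():
    rng = np.random.default_rng(1)
    lstm_branch = [nn.LSTM(1, 2, rng)]
    conv_branch = [nn.Permute(),
                   nn.Conv1D(10, 4, 3, rng),
                   nn.BatchNorm(4),
                   nn.GlobalAvgPool()]
    head = nn.Dense(2 + 4, 5, "softmax", rng)
    net = nn.TwoBranch(lstm_branch, conv_branch, head)
    X = rng.standard_normal((5, 10, 1))
    Y = np.eye(5)[rng.integers(0, 5, 5)]
    # keep BN in inference mode for a deterministic numeric check
    _, dlogits = nn.softmax_cross_entropy(net.forward(X, training=False), Y)
    net.backward(dlogits)
    for layer in net.layers:
        params = getattr(layer, "trainable_params", layer.params)
        for p, g in zip(params, layer.grads):
            assert np.max(np.abs(g - numeric_gradient(net, X, Y, p))) < 1e-6


def test_softmax_rows_sum_to_one():
    rng = np.random.default_rng(2)
    probs = nn.softmax(rng.standard_normal((40, 5)) * 10)
    assert np.max(np.abs(probs.sum(axis=1) - 1.0)) < 1e-6


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def test_split_is_deterministic_and_stratified():
    X, y = make_separable_dataset(500, "rri", seed=0)
    cfg = TrainConfig(epochs=1, seed=5)
    m1 = train(build_lstm_sequential(), labelled(X, y), cfg)
    m2 = train(build_lstm_sequential(), labelled(X, y), cfg)
    assert np.array_equal(m1.history["split"][0], m2.history["split"][0])
    # stratification keeps every class in the test split
    assert set(np.unique(m1.y_test)) == set(np.unique(y))


def test_single_class_input_rejected():
    X = np.random.default_rng(0).standard_normal((50, 9))
    with pytest.raises(ModelError):
        train(build_lstm_sequential(), (X, np.array(["N"] * 50)))


def test_training_learns_separable_classes():
    X, y = make_separable_dataset(1200, "rri", seed=3)
    model = train(build_lstm_sequential(), labelled(X, y),
                  TrainConfig(epochs=15, seed=3))
    report = evaluate(model)
    assert report.accuracy >= 0.9
    probs = model.predict_proba(X[:32])
    assert np.max(np.abs(probs.sum(axis=1) - 1.0)) < 1e-6


def test_feature_length_mismatch_rejected():
    X, y = make_separable_dataset(100, "rri", seed=0)
    with pytest.raises(ModelError):
        train(build_lstm_sequential(input_length=100), labelled(X, y))


def test_perfect_predictions_metrics():
    y = np.repeat(np.arange(5), 10)
    r = report_from_predictions(y, y)
    assert r.accuracy == r.precision == r.recall == r.f1 == 1.0
    assert np.array_equal(np.diag(r.confusion), np.full(5, 10))
    assert all(v == 1.0 for v in r.per_class_accuracy.values())


def test_constant_predictor_on_balanced_data():
    y = np.repeat(np.arange(5), 20)
    r = report_from_predictions(y, np.zeros_like(y))
    assert r.accuracy == pytest.approx(0.2)


def test_hand_built_confusion_metrics():
    # rows: true N,S; everything else absent
    y_true = np.array([0] * 8 + [1] * 2)
    y_pred = np.array([0] * 6 + [1] * 2 + [1, 1])
    r = report_from_predictions(y_true, y_pred)
    # N: 6/8 recall, S: 2/2; weighted recall = accuracy = 8/10
    assert r.accuracy == pytest.approx(0.8)
    assert r.recall == pytest.approx(0.8)
    assert r.per_class_accuracy["N"] == pytest.approx(0.75)
    assert r.per_class_accuracy["S"] == pytest.approx(1.0)
    # precision: N 6/6, S 2/4, weighted by support (8,2) -> .8*1 + .2*.5
    assert r.precision == pytest.approx(0.9)


def test_weighted_recall_equals_accuracy_property():
    rng = np.random.default_rng(7)
    for _ in range(20):
        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        r = report_from_predictions(y_true, y_pred)
        assert r.recall == pytest.approx(r.accuracy, abs=1e-12)


def test_empty_test_set_rejected():
    X, y = make_separable_dataset(200, "rri", seed=1)
    model = train(build_lstm_sequential(), labelled(X, y), TrainConfig(epochs=1))
    with pytest.raises(ModelError):
        evaluate(model, np.empty((0, 9)), np.array([], dtype=int))


def test_save_load_round_trip(tmp_path):
    X, y = make_separable_dataset(300, "rri", seed=2)
    model = train(build_lstm_sequential(), labelled(X, y), TrainConfig(epochs=2))
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    assert np.allclose(back.predict_proba(X[:20]), model.predict_proba(X[:20]))
    import json
    payload = json.loads((tmp_path / "m.json").read_text())
    assert payload["stream_batch_size"] == 1   # streaming export contract
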