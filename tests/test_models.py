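"""Cell equation oracles, training harness contracts and determinism."""

import numpy as np
import pytest

from pcgseg.io import SegmentDataset
from pcgseg.models import (
    GruCellParams,
    LstmCellParams,
    ModelConfig,
    SplitError,
    bigru_forward,
    gru_step,
    init_params,
    load_model,
    lstm_step,
    predict_labels,
    save_model,
    softmax,
    split_by_record,
    train,
)
from pcgseg.models.nets import FingerprintError, _forward

SIG = 1.0 / (1.0 + np.exp(-1.0))  # sigmoid(1) used in hand evaluations


def scalar_gru(w: float) -> GruCellParams:
    m = np.full((1, 1), w)
    return GruCellParams(m, m, m, m, m, m)


def hand_gru_step(p: GruCellParams, x, h):
    """Independent scalar evaluation of the gate equations."""

    def sig(a):
        return 1.0 / (1.0 + np.exp(-a))

    z = sig(p.w_zx[0, 0] * x + p.u_zh[0, 0] * h)
    r = sig(p.w_rx[0, 0] * x + p.u_rh[0, 0] * h)
    hc = np.tanh(p.w_hx[0, 0] * x + r * p.u_hh[0, 0] * h)
    return (1.0 - z) * hc + z * h


# ---------------------------------------------------------------------------
# GRU cell


def test_gru_zero_weights_halves_state():
    h = np.array([0.3, -0.7])
    zeros = np.zeros((2, 1))
    zh = np.zeros((2, 2))
    p = GruCellParams(zeros, zeros, zeros, zh, zh, zh)
    # z = r = 1/2 and the candidate is 0, so the new state is h/2
    np.testing.assert_allclose(gru_step(p, np.array([5.0]), h), 0.5 * h, atol=1e-15)


def test_gru_zero_input_zero_state():
    p = scalar_gru(0.1)
    assert gru_step(p, np.array([0.0]), np.array([0.0]))[0] == 0.0


def test_gru_scalar_hand_value():
    p = scalar_gru(0.1)
    out = gru_step(p, np.array([1.0]), np.array([0.0]))
    sig01 = 1.0 / (1.0 + np.exp(-0.1))
    expected = (1.0 - sig01) * np.tanh(0.1)
    assert out[0] == pytest.approx(expected, abs=1e-10)
    assert out[0] == pytest.approx(0.04734, abs=5e-6)


@pytest.mark.parametrize("w", [0.1, -0.3, 0.7])
def test_gru_scalar_unroll_matches_hand(w):
    p = scalar_gru(w)
    h_ref = 0.0
    h = np.array([0.0])
    for x in (1.0, -0.5, 0.25):
        h_ref = hand_gru_step(p, x, h_ref)
        h = gru_step(p, np.array([x]), h)
        assert h[0] == pytest.approx(h_ref, abs=1e-10)


# ---------------------------------------------------------------------------
# Bi-GRU


def test_bigru_zero_everything():
    zeros = np.zeros((3, 1))
    zh = np.zeros((3, 3))
    cell = GruCellParams(zeros, zeros, zeros, zh, zh, zh)
    out = bigru_forward(cell, cell, np.zeros((4, 1)))
    assert out.shape == (4, 6)
    np.testing.assert_array_equal(out, 0.0)


def test_bigru_length_one_input():
    fwd, bwd = scalar_gru(0.2), scalar_gru(-0.4)
    x = np.array([[0.7]])
    out = bigru_forward(fwd, bwd, x)
    np.testing.assert_allclose(out[0, 0], gru_step(fwd, x[0], np.zeros(1))[0])
    np.testing.assert_allclose(out[0, 1], gru_step(bwd, x[0], np.zeros(1))[0])


def test_bigru_length3_hand_unroll():
    """Scalar three-step case against an explicit forward/backward unroll."""
    fwd, bwd = scalar_gru(0.1), scalar_gru(0.3)
    xs = [1.0, -1.0, 0.5]
    out = bigru_forward(fwd, bwd, np.array(xs).reshape(3, 1))
    hf = 0.0
    fwd_states = []
    for x in xs:
        hf = hand_gru_step(fwd, x, hf)
        fwd_states.append(hf)
    hb = 0.0
    bwd_states = [0.0] * 3
    for t in (2, 1, 0):
        hb = hand_gru_step(bwd, xs[t], hb)
        bwd_states[t] = hb
    for t in range(3):
        assert out[t, 0] == pytest.approx(fwd_states[t], abs=1e-10)
        assert out[t, 1] == pytest.approx(bwd_states[t], abs=1e-10)


def test_bigru_reversal_symmetry(rng):
    """Reversing the input and swapping cells reverses the output halves."""
    def rand_cell():
        return GruCellParams(*(rng.standard_normal((2, 1)) for _ in range(3)),
                             *(rng.standard_normal((2, 2)) for _ in range(3)))

    fwd, bwd = rand_cell(), rand_cell()
    x = rng.standard_normal((5, 1))
    out = bigru_forward(fwd, bwd, x)
    swapped = bigru_forward(bwd, fwd, x[::-1])
    np.testing.assert_allclose(out[:, :2], swapped[::-1, 2:], atol=1e-12)
    np.testing.assert_allclose(out[:, 2:], swapped[::-1, :2], atol=1e-12)


# ---------------------------------------------------------------------------
# LSTM cell


def scalar_lstm(w: float) -> LstmCellParams:
    m = np.full((1, 1), w)
    return LstmCellParams(m, m, m, m, m, m, m, m)


def test_lstm_zero_everything():
    h, c = lstm_step(scalar_lstm(0.0), np.zeros(1), np.zeros(1), np.zeros(1))
    assert h[0] == 0.0 and c[0] == 0.0


def test_lstm_gate_semantics_perfect_memory():
    # forget gate forced to 1 (huge bias), input gate forced to 0
    big = np.full((1,), 100.0)
    p = LstmCellParams(
        *(np.zeros((1, 1)) for _ in range(8)),
        b_i=-big, b_f=big, b_o=np.zeros(1), b_g=np.zeros(1),
    )
    c_prev = np.array([0.42])
    _, c = lstm_step(p, np.array([1.0]), np.zeros(1), c_prev)
    np.testing.assert_allclose(c, c_prev, atol=1e-10)


def test_lstm_scalar_hand_value():
    p = scalar_lstm(0.5)
    h, c = lstm_step(p, np.array([2.0]), np.array([0.0]), np.array([0.0]))
    sig1 = 1.0 / (1.0 + np.exp(-1.0))
    g = np.tanh(1.0)
    c_exp = sig1 * g  # f*0 + i*g
    h_exp = sig1 * np.tanh(c_exp)
    assert c[0] == pytest.approx(c_exp, abs=1e-10)
    assert h[0] == pytest.approx(h_exp, abs=1e-10)


# ---------------------------------------------------------------------------
# Softmax


def test_softmax_uniform():
    np.testing.assert_allclose(softmax(np.zeros(4)), 0.25)


def test_softmax_hand_value():
    out = softmax(np.array([1.0, 0.0, 0.0, 0.0]))
    e = np.e
    np.testing.assert_allclose(out, [e / (e + 3), 1 / (e + 3), 1 / (e + 3), 1 / (e + 3)],
                               atol=1e-10)
    assert out[0] == pytest.approx(0.4754, abs=5e-5)


def test_softmax_overflow_safe():
    out = softmax(np.array([1000.0, 0.0, 0.0, 0.0]))
    assert np.all(np.isfinite(out))
    np.testing.assert_allclose(out, [1.0, 0.0, 0.0, 0.0], atol=1e-12)


def test_softmax_shift_invariance(rng):
    x = rng.standard_normal(4)
    np.testing.assert_allclose(softmax(x), softmax(x + 13.7), atol=1e-12)


def test_softmax_normalises(rng):
    for _ in range(10):
        assert softmax(rng.standard_normal(4) * 10).sum() == pytest.approx(1.0, abs=1e-12)


def test_softmax_rejects_nonfinite():
    with pytest.raises(ValueError):
        softmax(np.array([np.nan, 0.0, 0.0, 0.0]))


# ---------------------------------------------------------------------------
# Training harness


def toy_dataset(n_records=6, n_per=4, T=30, seed=0) -> SegmentDataset:
    """Separable task: the label tracks the sign pattern of the input."""
    rng = np.random.default_rng(seed)
    feats, labels, ids = [], [], []
    for r in range(n_records):
        for _ in range(n_per):
            x = rng.standard_normal(T)
            y = np.where(x > 0.5, 0, np.where(x > 0, 1, np.where(x > -0.5, 2, 3)))
            feats.append(x)
            labels.append(y)
            ids.append(f"rec{r}")
    return SegmentDataset(np.array(feats), np.array(labels), ids, 100, 0.3)


def test_train_learns_separable_task():
    ds = toy_dataset()
    cfg = ModelConfig(architecture="bigru", hidden_units=16, epochs=30, seed=0,
                      batch_size=4, learning_rate=0.01)
    model = train(ds, cfg)
    assert model.history["accuracy"][-1] > 0.95


def test_train_zero_epochs_is_noop():
    ds = toy_dataset()
    model = train(ds, ModelConfig(epochs=0, hidden_units=4, seed=0))
    assert model.history == {"loss": [], "accuracy": []}


def test_train_deterministic():
    ds = toy_dataset()
    cfg = ModelConfig(architecture="gru", hidden_units=8, epochs=3, seed=7)
    h1 = train(ds, cfg).history
    h2 = train(ds, cfg).history
    assert h1 == h2


def test_split_by_record_counts():
    ds = toy_dataset(n_records=10, n_per=1)
    train_ids, test_ids = split_by_record(ds, 0.7, seed=0)
    assert len(train_ids) == 7 and len(test_ids) == 3
    assert not set(train_ids) & set(test_ids)


def test_single_record_split_error():
    ds = toy_dataset(n_records=1)
    with pytest.raises(SplitError):
        train(ds, ModelConfig(hidden_units=4, epochs=1, seed=0))


def test_history_length_matches_epochs():
    ds = toy_dataset()
    model = train(ds, ModelConfig(architecture="bilstm", hidden_units=4, epochs=5,
                                  seed=1))
    assert len(model.history["loss"]) == 5
    assert len(model.history["accuracy"]) == 5


# ---------------------------------------------------------------------------
# Prediction


def test_predict_length_and_range():
    ds = toy_dataset()
    model = train(ds, ModelConfig(hidden_units=4, epochs=1, seed=0))
    seq = predict_labels(model, np.linspace(-1, 1, 57), rate=100)
    assert len(seq) == 57
    assert set(seq.labels) <= {0, 1, 2, 3}


def test_predict_constant_features_constant_labels():
    cfg = ModelConfig(hidden_units=4, epochs=0, seed=0, bias=False)
    params = init_params(cfg)
    for k in params:
        params[k] = np.zeros_like(params[k])
    from pcgseg.models import TrainedModel

    model = TrainedModel(architecture=cfg.architecture, config=cfg, params=params)
    seq = predict_labels(model, np.zeros(40))
    # all-zero scores: the tie breaks to the lowest class index everywhere
    assert set(seq.labels) == {0}


def test_fingerprint_mismatch_refused():
    ds = toy_dataset()
    model = train(ds, ModelConfig(hidden_units=4, epochs=0, seed=0),
                  fingerprint="aaaa")
    with pytest.raises(FingerprintError, match="fingerprint"):
        predict_labels(model, np.zeros(10), fingerprint="bbbb")


def test_checkpoint_round_trip(tmp_path):
    ds = toy_dataset()
    model = train(ds, ModelConfig(hidden_units=4, epochs=2, seed=0),
                  fingerprint="abcd")
    path = tmp_path / "model.npz"
    save_model(path, model)
    back = load_model(path)
    assert back.architecture == model.architecture
    assert back.fingerprint == "abcd"
    assert back.history == model.history
    x = np.linspace(-1, 1, 30)
    np.testing.assert_array_equal(back.predict_codes(x), model.predict_codes(x))


def test_batched_forward_matches_cells(rng):
    """The vectorised training path reproduces the reference cell math."""
    cfg = ModelConfig(architecture="bigru", hidden_units=3, seed=5, bias=False)
    p = init_params(cfg)
    T = 6
    X = rng.standard_normal((T, 1, 1))
    _, feats, _ = _forward(p, "bigru", X)
    fwd = GruCellParams(p["f.Wz"], p["f.Wr"], p["f.Wh"], p["f.Uz"], p["f.Ur"], p["f.Uh"])
    bwd = GruCellParams(p["b.Wz"], p["b.Wr"], p["b.Wh"], p["b.Uz"], p["b.Ur"], p["b.Uh"])
    ref = bigru_forward(fwd, bwd, X[:, 0, :])
    np.testing.assert_allclose(feats[:, 0, :], ref, atol=1e-12)
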