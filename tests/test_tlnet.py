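"""TL-embedding network: loss formulas against hand arithmetic, stage
contracts, training behaviour, reconstruction."""

import math

import numpy as np
import pytest

from radulna.core import DataError, StateError
from radulna.nn import MLP, Tensor
from radulna.tlnet import (
    TLNetConfig,
    TLNetState,
    label_loss,
    loss_step1,
    loss_step2,
    loss_step3,
    one_hot,
    reconstruct,
    train,
)


def hand_ce(logits_row, true_class):
    """Independent cross-entropy arithmetic: ln(sum exp) - logit[true]."""
    m = max(logits_row)
    return math.log(sum(math.exp(v - m) for v in logits_row)) - (
        logits_row[true_class] - m
    )


class TestLabelLoss:
    def test_uniform_logits_give_ln3(self):
        logits = np.zeros((5, 5, 3))
        y = np.random.default_rng(0).integers(0, 3, (5, 5))
        assert label_loss(logits, y) == pytest.approx(math.log(3.0), abs=1e-12)

    def test_saturated_true_class_near_zero(self):
        y = np.array([[0, 1], [2, 1]])
        logits = one_hot(y, 3) * 1e4
        assert label_loss(logits, y) < 1e-4

    def test_two_voxel_hand_oracle(self):
        logits = np.array([[0.3, -1.2, 0.7], [2.0, 0.1, -0.5]])
        y = np.array([2, 0])
        expected = (hand_ce([0.3, -1.2, 0.7], 2) + hand_ce([2.0, 0.1, -0.5], 0)) / 2
        assert label_loss(logits, y) == pytest.approx(expected, abs=1e-6)

    def test_bad_class_rejected(self):
        with pytest.raises(DataError):
            label_loss(np.zeros((2, 3)), np.array([0, 5]))


def toy_encoder_decoder():
    """1-voxel, 2-class, 2-d latent nets with hand-set weights."""
    rng = np.random.default_rng(0)
    enc = MLP([2, 2], rng)
    dec = MLP([2, 2], rng)
    enc.layers[0].W.data = np.array([[0.5, -1.0], [2.0, 0.25]])
    enc.layers[0].b.data = np.array([0.1, -0.2])
    dec.layers[0].W.data = np.array([[1.5, -0.5], [0.0, 1.0]])
    dec.layers[0].b.data = np.array([-0.3, 0.4])
    return enc, dec


class TestStep1:
    def test_toy_hand_computation(self):
        enc, dec = toy_encoder_decoder()
        y = np.array([[1]])  # one voxel, true class 1
        y_noised = np.array([[0.9, 0.15]])  # corrupted one-hot
        lam = 0.01
        # hand arithmetic
        z = y_noised @ np.array([[0.5, -1.0], [2.0, 0.25]]) + np.array([0.1, -0.2])
        logits = z @ np.array([[1.5, -0.5], [0.0, 1.0]]) + np.array([-0.3, 0.4])
        expected = hand_ce(list(logits[0]), 1) + lam * np.abs(z).sum()
        got = loss_step1(y, y_noised, enc, dec, lam, n_classes=2)
        assert got.item() == pytest.approx(expected, abs=1e-6)

    def test_lambda_zero_leaves_label_term(self):
        enc, dec = toy_encoder_decoder()
        y = np.array([[0]])
        y_noised = one_hot(y, 2).reshape(1, -1)
        with_reg = loss_step1(y, y_noised, enc, dec, 1.0, n_classes=2).item()
        without = loss_step1(y, y_noised, enc, dec, 0.0, n_classes=2).item()
        logits = dec(enc(Tensor(y_noised)))
        assert without == pytest.approx(label_loss(logits.data, y), abs=1e-9)
        assert with_reg > without

    def test_zero_latent_kills_l1_term(self):
        enc, dec = toy_encoder_decoder()
        enc.layers[0].W.data[:] = 0.0
        enc.layers[0].b.data[:] = 0.0
        y = np.array([[1]])
        y_noised = one_hot(y, 2).reshape(1, -1)
        a = loss_step1(y, y_noised, enc, dec, 0.0, n_classes=2).item()
        b = loss_step1(y, y_noised, enc, dec, 100.0, n_classes=2).item()
        assert a == pytest.approx(b, abs=1e-12)


class TestStep2:
    def test_substitution_identity_with_stage1(self):
        """With lambda1 = 0 and P(x) forced equal to E(y), the stage-2 loss
        equals the stage-1 label term on the clean sample."""
        enc, dec = toy_encoder_decoder()
        y = np.array([[1]])
        y_oh = one_hot(y, 2).reshape(1, -1)
        predictor = lambda x: enc(Tensor(y_oh))  # noqa: E731
        s2 = loss_step2(np.zeros((1, 4)), y, predictor, dec, 0.0, n_classes=2)
        s1 = loss_step1(y, y_oh, enc, dec, 0.0, n_classes=2)
        assert s2.item() == pytest.approx(s1.item(), abs=1e-12)

    def test_toy_hand_computation(self):
        enc, dec = toy_encoder_decoder()
        x = np.array([[0.4, -0.6]])
        y = np.array([[0]])
        lam = 0.02
        z = x @ np.array([[0.5, -1.0], [2.0, 0.25]]) + np.array([0.1, -0.2])
        logits = z @ np.array([[1.5, -0.5], [0.0, 1.0]]) + np.array([-0.3, 0.4])
        expected = hand_ce(list(logits[0]), 0) + lam * np.abs(z).sum()
        got = loss_step2(x, y, enc, dec, lam, n_classes=2)
        assert got.item() == pytest.approx(expected, abs=1e-6)

    def test_loss_nonnegative(self):
        enc, dec = toy_encoder_decoder()
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=(1, 2))
            y = np.array([[seed % 2]])
            assert loss_step2(x, y, enc, dec, 0.1, n_classes=2).item() >= 0

    def test_unfrozen_decoder_rejected(self):
        enc, dec = toy_encoder_decoder()
        with pytest.raises(StateError):
            loss_step2(np.zeros((1, 2)), np.array([[0]]), enc, dec, 0.0,
                       n_classes=2, decoder_frozen=False)


class TestStep3:
    def test_lambda2_zero_equals_step2(self):
        enc, dec = toy_encoder_decoder()
        x = np.array([[0.4, -0.6]])
        y = np.array([[1]])
        s3 = loss_step3(x, y, enc, dec, enc, 0.05, 0.0, n_classes=2)
        s2 = loss_step2(x, y, enc, dec, 0.05, n_classes=2)
        assert s3.item() == pytest.approx(s2.item(), abs=1e-12)

    def test_perfect_reconstruction_zeroes_consistency(self):
        """If softmax(D(P(x))) reproduces y exactly, the consistency term
        vanishes and step 3 reduces to its first two terms."""
        enc, _ = toy_encoder_decoder()
        y = np.array([[1]])
        y_oh = one_hot(y, 2).reshape(1, -1)
        saturated = lambda z: Tensor(one_hot(y, 2).reshape(1, -1) * 1e4)  # noqa: E731
        predictor = lambda x: Tensor(np.zeros((1, 2)))  # noqa: E731
        s3 = loss_step3(np.zeros((1, 2)), y, enc, saturated, predictor,
                        0.0, 5.0, n_classes=2)
        s2 = loss_step2(np.zeros((1, 2)), y, predictor, saturated, 0.0,
                        n_classes=2)
        assert s3.item() == pytest.approx(s2.item(), abs=1e-9)

    def test_toy_hand_computation(self):
        enc, dec = toy_encoder_decoder()
        We = np.array([[0.5, -1.0], [2.0, 0.25]])
        be = np.array([0.1, -0.2])
        Wd = np.array([[1.5, -0.5], [0.0, 1.0]])
        bd = np.array([-0.3, 0.4])
        x = np.array([[0.4, -0.6]])
        y = np.array([[1]])
        lam1, lam2 = 0.01, 0.5
        z = x @ We + be
        logits = z @ Wd + bd
        probs = np.exp(logits - logits.max())
        probs = probs / probs.sum()
        e_y = np.array([[0.0, 1.0]]) @ We + be
        e_rec = probs @ We + be
        expected = (
            hand_ce(list(logits[0]), 1)
            + lam1 * np.abs(z).sum()
            + lam2 * np.sqrt(((e_y - e_rec) ** 2).sum())
        )
        got = loss_step3(x, y, enc, dec, enc, lam1, lam2, n_classes=2)
        assert got.item() == pytest.approx(expected, abs=1e-6)

    def test_squared_variant_squares_consistency(self):
        enc, dec = toy_encoder_decoder()
        x = np.array([[0.4, -0.6]])
        y = np.array([[1]])
        base = loss_step2(x, y, enc, dec, 0.0, n_classes=2).item()
        lin = loss_step3(x, y, enc, dec, enc, 0.0, 1.0, n_classes=2).item()
        sq = loss_step3(x, y, enc, dec, enc, 0.0, 1.0, n_classes=2,
                        squared=True).item()
        assert sq - base == pytest.approx((lin - base) ** 2, rel=1e-9)

    def test_unfrozen_encoder_rejected(self):
        enc, dec = toy_encoder_decoder()
        with pytest.raises(StateError):
            loss_step3(np.zeros((1, 2)), np.array([[0]]), enc, dec, enc,
                       0.0, 0.0, n_classes=2, encoder_frozen=False)


def tiny_config(**over):
    base = dict(
        label_shape=(8, 8, 8),
        image_shape=(16, 16),
        latent_dim=16,
        encoder_hidden=(32,),
        decoder_hidden=(32,),
        predictor_hidden=(32,),
        stage_iters=(2, 2, 2),
        batch_size=4,
        seed=0,
    )
    base.update(over)
    return TLNetConfig(**base)


def tiny_dataset(n=4, seed=0):
    rng = np.random.default_rng(seed)
    images = rng.uniform(0, 1, (n, 16, 16))
    labels = np.zeros((n, 8, 8, 8), dtype=np.uint8)
    for i in range(n):
        labels[i, 2 : 4 + i % 3, 2:6, 1:7] = 1
        labels[i, 5:7, 2:6, 1:7] = 2
    return images, labels


class TestTraining:
    def test_smoke_run_logs_every_step(self):
        images, labels = tiny_dataset()
        state = train(images, labels, tiny_config())
        assert len(state.logs) == 6
        assert state.stages_completed == [1, 2, 3]

    def test_freezing_contracts_bitwise(self):
        images, labels = tiny_dataset()
        state = train(images, labels, tiny_config(stage_iters=(3, 3, 3)))
        cs = state.checksums
        # decoder untouched during stage 2
        assert cs["stage1"]["decoder"] == cs["stage2"]["decoder"]
        # encoder untouched during stages 2 and 3
        assert cs["stage1"]["encoder"] == cs["stage2"]["encoder"]
        assert cs["stage1"]["encoder"] == cs["stage3"]["encoder"]
        # the trained parts actually moved in their stages
        assert cs["init"]["encoder"] != cs["stage1"]["encoder"]
        assert cs["stage1"]["predictor"] != cs["stage2"]["predictor"]
        assert cs["stage2"]["decoder"] != cs["stage3"]["decoder"]

    def test_stage1_loss_descends(self):
        images, labels = tiny_dataset(n=6)
        cfg = tiny_config(stage_iters=(200, 1, 1), stage_lrs=(1e-3, 1e-4, 1e-5))
        state = train(images, labels, cfg)
        s1 = [r["loss"] for r in state.logs if r["stage"] == 1]
        assert s1[199] < s1[0]

    def test_determinism(self):
        images, labels = tiny_dataset()
        a = train(images, labels, tiny_config())
        b = train(images, labels, tiny_config())
        assert a.encoder.state_bytes() == b.encoder.state_bytes()
        assert a.predictor.state_bytes() == b.predictor.state_bytes()

    def test_l1_weight_shrinks_latents(self):
        """Raising lambda1 100x yields smaller mean |P(x)|_1 after stage 2."""
        images, labels = tiny_dataset(n=6)
        norms = {}
        for lam in (1e-4, 1e-2):
            cfg = tiny_config(lambda1=lam, stage_iters=(150, 400, 1),
                              stage_lrs=(1e-3, 1e-3, 1e-5))
            state = train(images, labels, cfg)
            z = state.predictor(Tensor(images.reshape(len(images), -1))).data
            norms[lam] = np.abs(z).sum(axis=1).mean()
        assert norms[1e-2] < norms[1e-4]


class TestReconstruct:
    @pytest.fixture(scope="class")
    def trained(self):
        images, labels = tiny_dataset(n=6)
        cfg = tiny_config(stage_iters=(300, 600, 100),
                          stage_lrs=(1e-3, 1e-3, 1e-4))
        return train(images, labels, cfg), images, labels

    def test_deterministic_and_valid_classes(self, trained):
        state, images, _ = trained
        a = reconstruct(images[0], state)
        b = reconstruct(images[0], state)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        assert set(np.unique(a.voxels)) <= {0, 1, 2}

    def test_memorizes_training_sample(self, trained):
        """After scaled-down training, the radius Dice on a training sample
        clears the memorization sanity bound."""
        state, images, labels = trained
        pred = reconstruct(images[0], state)
        a = pred.voxels == 1
        b = labels[0] == 1
        dice = 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
        assert dice > 0.7

    def test_untrained_predictor_rejected(self):
        cfg = tiny_config()
        state = TLNetState.initialize(cfg)
        with pytest.raises(StateError, match="untrained"):
            reconstruct(np.zeros(cfg.image_shape), state)

    def test_nonfinite_loss_aborts_with_stage(self):
        images, labels = tiny_dataset()
        images[0, 0, 0] = np.inf
        with pytest.raises(StateError, match="stage 2"):
            train(images, labels, tiny_config(stage_iters=(1, 50, 1)))
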