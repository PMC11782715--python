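import numpy as np
import pytest

from walinet.model import (
    TrainConfig,
    YNet,
    YNetConfig,
    augment_phase,
    build_ynet,
    infer_nuisance,
    learning_rate,
    load_checkpoint,
    normalize_pair,
    save_checkpoint,
    train,
)
from walinet.model import _subject_split
from walinet.spectrum import Spectrum


class TestConfig:
    def test_default_encoder_channel_progression(self):
        assert YNetConfig().encoder_channels == [16, 32, 64, 128]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            YNetConfig(depth=0)
        with pytest.raises(ValueError):
            YNetConfig(base_channels=0)
        with pytest.raises(ValueError):
            YNetConfig(kernel_size=4)
        with pytest.raises(ValueError):
            TrainConfig(mode="both")

    def test_published_learning_rate_schedule(self):
        """lr(100) = 0.01 * 0.25**2 with quartering every 50 epochs."""
        cfg = TrainConfig(epochs=400)
        assert cfg.lr_decay_every == 50
        assert learning_rate(cfg, 0) == 0.01
        assert learning_rate(cfg, 100) == pytest.approx(0.000625)
        assert learning_rate(cfg, 399) == pytest.approx(0.01 * 0.25**7)


class TestArchitecture:
    def test_forward_preserves_length_and_finiteness(self):
        net = build_ynet(YNetConfig(base_channels=4))
        x = np.zeros((2, 2, 453), dtype=np.float32)
        out = net.forward(x, x)
        assert out.data.shape == (2, 2, 453)
        assert np.all(np.isfinite(out.data))

    @pytest.mark.parametrize("length", [448, 453, 464])
    def test_arbitrary_lengths_pad_and_crop(self, length):
        net = build_ynet(YNetConfig(base_channels=2))
        x = np.random.default_rng(0).standard_normal((1, 2, length)).astype(np.float32)
        assert net.forward(x, x).data.shape[-1] == length

    def test_parameter_count_toy_config_hand_sum(self):
        """depth 2, base 4, kernel 3: layer-by-layer analytic count."""
        cfg = YNetConfig(depth=2, base_channels=4, kernel_size=3)
        net = YNet(cfg)

        def conv(ci, co, k=3):
            return co * ci * k + co

        def block(ci, co):
            return conv(ci, co) + conv(co, co) + 2 * co  # two convs + two PReLU

        expected = 0
        expected += block(2, 4) + block(4, 8)  # encoder 1
        expected += block(2, 4) + block(4, 8)  # encoder 2
        expected += block(16, 8)  # bottleneck on concatenated streams
        expected += block(8 + 8 + 8, 4)  # decoder level 2 (up + two skips)
        expected += block(4 + 4 + 4, 4)  # decoder level 1
        expected += block(4, 4)  # final block
        expected += conv(4, 2)  # output projection
        assert net.n_parameters() == expected

    def test_deterministic_initialization(self):
        a = YNet(YNetConfig(base_channels=2), seed=3)
        b = YNet(YNetConfig(base_channels=2), seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)


class TestNormalization:
    def test_hand_vectors(self):
        x1p, x2p, e = normalize_pair(np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        assert e == 1.0
        assert np.allclose(x1p, [1.0, 0.0])

    def test_degenerate_equal_inputs_use_eps_floor(self):
        x = np.array([1.0 + 1j, 2.0])
        x1p, x2p, e = normalize_pair(x, x)
        assert e == 0.0
        assert np.all(np.isfinite(x1p)) and np.all(np.isfinite(x2p))

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        x1 = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        x2 = rng.standard_normal(8)
        n1, n2, e = normalize_pair(x1, x2)
        m1, m2, ec = normalize_pair(3.0 * x1, 3.0 * x2)
        assert ec == pytest.approx(3.0 * e)
        assert np.allclose(m1, n1) and np.allclose(m2, n2)


class TestAugmentation:
    def test_zero_phase_is_identity(self):
        x = np.array([1.0 + 2j, -3.0])
        (out,), om = augment_phase((x,), omega=0.0)
        assert om == 0.0
        assert np.array_equal(out, x)

    def test_magnitudes_preserved_and_shared_phase(self, rng):
        x = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        y = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        (xa, ya), om = augment_phase((x, y), rng=rng)
        assert 0.0 <= om < 2 * np.pi
        assert np.allclose(np.abs(xa), np.abs(x))
        # same omega applied to both arrays
        assert np.allclose(xa / x, ya / y)


class TestTraining:
    def test_zero_epochs_leaves_weights_unchanged(self, small_dataset):
        net = build_ynet(YNetConfig(base_channels=2))
        before = [p.data.copy() for p in net.parameters()]
        _, history = train(net, small_dataset, TrainConfig(epochs=0, seed=0))
        assert history == []
        for p, b in zip(net.parameters(), before):
            assert np.array_equal(p.data, b)

    def test_overfit_small_subset_reduces_loss_tenfold(self, small_dataset):
        """200 gradient steps on 10 examples shrink the loss >= 10x."""
        import dataclasses

        sub = dataclasses.replace(
            small_dataset,
            m=small_dataset.m[:10],
            lipid=small_dataset.lipid[:10],
            water=small_dataset.water[:10],
            x1=small_dataset.x1[:10],
            x2=small_dataset.x2[:10],
            subject_ids=small_dataset.subject_ids[:10],
        )
        net = build_ynet(YNetConfig(base_channels=4, dropout_rate=0.0))
        cfg = TrainConfig(
            epochs=200, batch_size=10, seed=1, val_fraction=0.0,
            lr=3e-3, lr_decay_every=10_000,
        )
        _, history = train(net, sub, cfg)
        first = history[0]["train_loss"]
        last = min(h["train_loss"] for h in history[-5:])
        assert last <= first / 10.0

    def test_subject_split_hygiene(self):
        subjects = np.repeat(np.arange(10), 5)
        tr, val = _subject_split(subjects, 0.2, np.random.default_rng(0))
        assert val.size > 0
        assert set(subjects[tr]).isdisjoint(set(subjects[val]))

    def test_seeded_training_is_reproducible(self, small_dataset):
        histories = []
        for _ in range(2):
            net = build_ynet(YNetConfig(base_channels=2))
            _, h = train(net, small_dataset, TrainConfig(epochs=1, batch_size=16, seed=4))
            histories.append(h)
        a, b = histories
        assert abs(a[0]["train_loss"] - b[0]["train_loss"]) < 1e-6

    def test_empty_dataset_rejected(self, small_dataset):
        import dataclasses

        empty = dataclasses.replace(
            small_dataset,
            m=small_dataset.m[:0], lipid=small_dataset.lipid[:0],
            water=small_dataset.water[:0], x1=small_dataset.x1[:0],
            x2=small_dataset.x2[:0], subject_ids=small_dataset.subject_ids[:0],
        )
        with pytest.raises(ValueError, match="empty"):
            train(build_ynet(YNetConfig(base_channels=2)), empty, TrainConfig(epochs=1))


class _OracleNet:
    """Stub that returns a fixed target regardless of input."""

    dtype = np.float32

    def __init__(self, target):
        self.target = target

    def predict(self, b1, b2):
        scale = np.float32(1.0)
        return np.broadcast_to(
            np.stack([self.target.real, self.target.imag])[None], (b1.shape[0], 2, self.target.size)
        ).astype(np.float32)


class TestInference:
    def test_oracle_network_subtraction_identity(self, small_dataset):
        """If the net outputs its target exactly, m~ = x1 - (l + w)."""
        axis = small_dataset.axis
        i = 0
        sid = int(small_dataset.subject_ids[i])
        sub = small_dataset.subspaces[sid]
        x1 = small_dataset.x1[i]
        x2 = sub.project(x1)
        e = np.linalg.norm(x1 - x2)
        target = (small_dataset.lipid[i] + small_dataset.water[i]) / e
        net = _OracleNet(target.astype(np.complex64))
        y, m_hat = infer_nuisance(net, Spectrum(x1, axis, "freq"), sub)
        expect = x1 - (small_dataset.lipid[i] + small_dataset.water[i])
        # float32 stub limits agreement; identity holds to single precision
        assert (
            np.abs(m_hat.data - expect).max()
            < 1e-5 * np.abs(small_dataset.x1[i]).max()
        )

    def test_inference_scale_invariant(self, small_dataset):
        """Energy normalization makes y(c x1) = c y(x1) within 5%."""
        axis = small_dataset.axis
        sid = int(small_dataset.subject_ids[0])
        sub = small_dataset.subspaces[sid]
        net = build_ynet(YNetConfig(base_channels=2), seed=0)
        x1 = Spectrum(small_dataset.x1[0], axis, "freq")
        y_ref, _ = infer_nuisance(net, x1, sub)
        for c in (0.1, 10.0):
            y_c, _ = infer_nuisance(net, c * x1, sub)
            rel = np.linalg.norm(y_c.data - c * y_ref.data) / np.linalg.norm(
                c * y_ref.data
            )
            assert rel < 0.05

    def test_axis_mismatch_rejected(self, small_dataset):
        from walinet.axis import SpectralAxis

        other = SpectralAxis(n_points=64, bandwidth_hz=1000.0)
        net = build_ynet(YNetConfig(base_channels=2))
        sid = int(small_dataset.subject_ids[0])
        with pytest.raises(ValueError, match="axis"):
            infer_nuisance(
                net,
                Spectrum(np.zeros(64, complex), other, "freq"),
                small_dataset.subspaces[sid],
            )


def test_checkpoint_round_trip(tmp_path, small_dataset):
    net = build_ynet(YNetConfig(base_channels=2), seed=5)
    cfg = TrainConfig(epochs=1, seed=5)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, net, train_config=cfg, axis=small_dataset.axis)
    loaded, meta = load_checkpoint(path)
    assert meta["axis"]["n_points"] == small_dataset.axis.n_points
    for pa, pb in zip(net.parameters(), loaded.parameters()):
        assert np.array_equal(pa.data, pb.data)
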