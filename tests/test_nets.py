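import numpy as np
import pytest

from ecgtracks import nets, nn
from ecgtracks.io import EcgRecord


@pytest.fixture(scope="module")
def cnn1d_bundle():
    return nets.build_cnn1d(4, input_len=8999)


@pytest.fixture(scope="module")
def resnet1d_bundle():
    return nets.build_resnet1d(4)


class TestCnn1dAudit:
    def test_twelve_blocks(self, cnn1d_bundle):
        desc = cnn1d_bundle.describe()["root"]
        blocks = [l for l in desc["layers"] if l["name"].startswith("block")]
        assert len(blocks) == 12

    def test_kernel_schedule(self, cnn1d_bundle):
        desc = cnn1d_bundle.describe()["root"]
        kernels = [l["layers"][0]["kernel"] for l in desc["layers"]
                   if l["name"].startswith("block")]
        assert kernels == [20] + [5] * 5 + [3] * 6

    def test_channel_schedule_endpoints(self, cnn1d_bundle):
        desc = cnn1d_bundle.describe()["root"]
        chans = [l["layers"][0]["out_channels"] for l in desc["layers"]
                 if l["name"].startswith("block")]
        assert chans[0] == 256 and chans[-1] == 32
        assert all(a >= b for a, b in zip(chans, chans[1:]))  # monotone taper

    def test_block_layout(self, cnn1d_bundle):
        desc = cnn1d_bundle.describe()["root"]
        block = desc["layers"][0]["layers"]
        types = [l["type"] for l in block]
        assert types == ["Conv1d", "BatchNorm", "ReLU", "MaxPool1d", "Dropout"]
        assert block[0]["stride"] == 1 and block[0]["padding"] == 0
        assert block[1]["momentum"] == 0.99
        assert block[3]["kernel"] == 2 and block[3]["stride"] == 2
        assert block[4]["p"] == 0.3

    def test_head_avgpool_k1_s2(self, cnn1d_bundle):
        head = cnn1d_bundle.describe()["root"]["layers"][-1]["layers"]
        assert head[0]["type"] == "AvgPool1d"
        assert head[0]["kernel"] == 1 and head[0]["stride"] == 2
        assert head[-1]["out_features"] == 4

    def test_forward_shape_and_finiteness(self, cnn1d_bundle):
        x = np.random.default_rng(0).standard_normal((2, 1, 8999))
        out = cnn1d_bundle.net.forward(x)
        assert out.shape == (2, 4) and np.isfinite(out).all()

    def test_too_short_input_reports_minimum(self):
        with pytest.raises(ValueError, match=str(nets.cnn1d_min_length())):
            nets.build_cnn1d(4, input_len=3000)


class TestResnet1dAudit:
    def test_stem(self, resnet1d_bundle):
        stem = resnet1d_bundle.describe()["root"]["layers"][0]["layers"]
        assert stem[0]["kernel"] == 15 and stem[0]["out_channels"] == 64
        assert [l["type"] for l in stem] == ["Conv1d", "BatchNorm", "ReLU",
                                             "MaxPool1d"]

    def test_four_residual_blocks(self, resnet1d_bundle):
        desc = resnet1d_bundle.describe()["root"]
        blocks = [l for l in desc["layers"] if l["type"] == "ResBlock1d"]
        assert len(blocks) == 4
        assert [b["channels"] for b in blocks] == [64, 128, 192, 256]

    def test_dual_pool_concat_head(self, resnet1d_bundle):
        head = resnet1d_bundle.describe()["root"]["layers"][-1]["layers"]
        assert head[0]["type"] == "DualPoolConcat1d"
        assert head[0]["pools"] == ["avg", "max"]
        assert head[1]["in_features"] == 512  # 2 x last block channels

    def test_residual_passthrough(self):
        """With zeroed weights and identity BN, a block outputs ReLU(input)."""
        block = nets.ResBlock1d(8, 8, 7, rng=np.random.default_rng(0))
        for conv in (block.conv1, block.conv2):
            conv.w.value[...] = 0.0
            conv.b.value[...] = 0.0
        for bn in (block.bn1, block.bn2):
            bn.running_mean[...] = 0.0
            bn.running_var[...] = 1.0 - bn.eps
        block.set_training(False)
        x = np.random.default_rng(1).standard_normal((2, 8, 20))
        assert np.allclose(block(x), np.maximum(x, 0.0), atol=1e-6)


class TestImage2dAudit:
    @pytest.mark.parametrize("backbone,params", [
        ("densenet121", 6_968_196), ("resnet50", 23_535_108)])
    def test_canonical_parameter_counts(self, backbone, params):
        b = nets.build_image2d(backbone, 4)
        assert sum(p.value.size for p in b.net.parameters()) == params

    @pytest.mark.parametrize("backbone", ["densenet121", "resnet50"])
    def test_final_layer_matches_classes(self, backbone):
        for n_classes in (4, 9):
            b = nets.build_image2d(backbone, n_classes, width_scale=0.125,
                                   depth_scale=0.25)
            head = b.describe()["root"]["layers"][-1]
            assert head["type"] == "Linear"
            assert head["out_features"] == n_classes

    def test_forward_logits_shape(self):
        b = nets.build_image2d("densenet121", 4, image_size=32,
                               width_scale=0.125, depth_scale=0.25)
        x = np.random.default_rng(0).standard_normal((3, 3, 32, 32))
        out = b.net.forward(x)
        assert out.shape == (3, 4) and np.isfinite(out).all()

    def test_untrained_predictions_near_uniform(self):
        b = nets.build_image2d("resnet50", 4, image_size=32,
                               width_scale=0.125, depth_scale=0.25, seed=3)
        x = np.abs(np.random.default_rng(0).standard_normal((40, 3, 32, 32)))
        proba = b.net.predict_proba(x)
        mean_entropy = -np.mean(np.sum(proba * np.log(proba + 1e-12), axis=1))
        assert mean_entropy > 0.8 * np.log(4)

    def test_twelve_lead_input_enters_as_channels(self):
        from ecgtracks import synth

        rec, _ = synth.simulate_record(
            synth.RhythmSpec.for_class("sinus", seed=2), duration_s=6.0,
            fs=500.0, n_leads=12)
        b = nets.build_resnet1d(4, n_leads=12, width_scale=0.0625)
        x = nets.prepare_input(b, rec, target_fs=500.0, window_s=6.0)
        assert x.shape == (12, 2999)
        out = b.net.forward(x[None])
        assert out.shape == (1, 4) and np.isfinite(out).all()

    def test_unknown_backbone(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            nets.build_image2d("vgg16", 4)


@pytest.fixture(scope="module")
def tiny_trained():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 1, 400)).astype(np.float32)
    y = (X.mean(axis=(1, 2)) > 0).astype(int)
    b = nets.build_resnet1d(2, width_scale=0.0625, seed=0)
    b.classes = ["neg", "pos"]
    nets.train(b, (X[:40], y[:40]), (X[40:], y[40:]),
               nets.TrainConfig(epochs=2, seed=0))
    return b, X


class TestPredict:

    def test_multiclass_rows_sum_to_one(self, tiny_trained):
        b, X = tiny_trained
        proba = nets.predict(b, X[:10])
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_equals_concatenated_singles(self, tiny_trained):
        b, X = tiny_trained
        batch = nets.predict(b, X[:6])
        singles = np.concatenate([nets.predict(b, X[i : i + 1])
                                  for i in range(6)])
        assert np.allclose(batch, singles, atol=1e-6)

    def test_amplitude_scale_invariance(self, tiny_trained):
        """z-scored differences erase lead-wise amplitude scaling."""
        b, _ = tiny_trained
        rng = np.random.default_rng(5)
        sig = rng.standard_normal((1, 401))
        rec = EcgRecord(record_id="a", signal=sig, fs=40.0, lead_names=["I"],
                        labels={"pos"})
        rec2 = EcgRecord(record_id="b", signal=5.0 * sig, fs=40.0,
                         lead_names=["I"], labels={"pos"})
        x1 = nets.prepare_input(b, rec, target_fs=40.0, window_s=10.0)
        x2 = nets.prepare_input(b, rec2, target_fs=40.0, window_s=10.0)
        p1 = nets.predict(b, x1[None])
        p2 = nets.predict(b, x2[None])
        assert np.allclose(p1, p2, atol=1e-5)

    def test_untrained_warns(self, caplog):
        b = nets.build_resnet1d(2, width_scale=0.0625)
        with caplog.at_level("WARNING"):
            nets.predict(b, np.zeros((1, 1, 100)))
        assert "untrained" in caplog.text

    def test_multilabel_scores_in_unit_interval(self):
        b = nets.build_resnet1d(3, width_scale=0.0625, mode="multilabel")
        b.classes = ["a", "b", "c"]
        proba = b.net.predict_proba(
            np.random.default_rng(0).standard_normal((4, 1, 200)))
        assert np.all((proba >= 0) & (proba <= 1))
        decided = nets.decide(b, proba)
        assert all(isinstance(d, set) and d for d in decided)


class TestTraining:
    def test_fixed_seed_reproducible_first_epoch(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 1, 300)).astype(np.float32)
        y = rng.integers(0, 2, 40)
        losses = []
        for _ in range(2):
            b = nets.build_resnet1d(2, width_scale=0.0625, seed=7)
            nets.train(b, (X[:30], y[:30]), (X[30:], y[30:]),
                       nets.TrainConfig(epochs=1, seed=7))
            losses.append(b.history[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_loss_decreases_on_learnable_task(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 1, 300)).astype(np.float32)
        y = (X[:, 0, :50].mean(axis=1) > 0).astype(int)
        X[y == 1, :, 100:150] += 2.0
        b = nets.build_resnet1d(2, width_scale=0.0625, seed=1)
        nets.train(b, (X[:60], y[:60]), (X[60:], y[60:]),
                   nets.TrainConfig(epochs=4, seed=1))
        assert b.history[-1]["train_loss"] < b.history[0]["train_loss"]

    @pytest.mark.timeout(900)
    def test_cnn1d_recovers_texture_contrast(self):
        """The 12-block CNN separates clean sinus rhythm from heavily
        noise-corrupted rhythm — a local-texture contrast suited to its
        all-max-pooling layout — well above chance on held-out records."""
        from ecgtracks import bench

        out = bench.cnn1d_recovery(seed=20)
        assert out["test_macro_f1"] >= 0.85

    def test_empty_set_rejected(self):
        b = nets.build_resnet1d(2, width_scale=0.0625)
        with pytest.raises(ValueError):
            nets.train(b, (np.zeros((0, 1, 10)), np.zeros(0)),
                       (np.zeros((1, 1, 10)), np.zeros(1)))
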