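"""Asymmetric loss, pseudo-labels, mining, session handling, training loop."""

import math

import numpy as np
import pytest
from conftest import STRIDE, build_stream
from hypothesis import given, settings
from hypothesis import strategies as st

import holoctc as h
from holoctc.detect import (Heatmap, Keypoint, extract_keypoints,
                            predict_heatmap, render_targets)
from holoctc.net import HeatmapNet
from holoctc.train import (SampleStream, SessionLossLedger, TrainConfig,
                           asymmetric_bce, make_pseudo_labels,
                           mine_hard_samples, session_weighted_sampler,
                           split_sessions, train_detector)
from holoctc.validate import match_detections

OPTICS = h.OpticalConfig(roi_px=(256, 96), defocus_um=30.0)


class TestAsymmetricLoss:
    def test_perfect_prediction_near_zero(self):
        y = np.ones((4, 4))
        p = np.full((4, 4), 1.0 - 1e-7)
        assert asymmetric_bce(p, y, "positive") < 1e-5

    def test_false_positive_on_positive_stream(self):
        loss = asymmetric_bce(np.array([[0.5]]), np.array([[0.0]]), "positive")
        assert loss == pytest.approx(0.1 * math.log(2), rel=1e-9)

    def test_false_positive_on_negative_stream(self):
        loss = asymmetric_bce(np.array([[0.5]]), np.array([[0.0]]), "negative")
        assert loss == pytest.approx(math.log(2), rel=1e-9)

    def test_asymmetry_ratio_is_exactly_A(self):
        p = np.array([[0.5]])
        y = np.array([[0.0]])
        ratio = asymmetric_bce(p, y, "positive") / asymmetric_bce(p, y, "negative")
        assert ratio == pytest.approx(0.1, rel=1e-12)

    def test_true_positive_pixels_keep_full_weight(self):
        # y above the cutoff: both streams weigh the pixel identically
        p = np.array([[0.3]])
        y = np.array([[0.9]])
        assert asymmetric_bce(p, y, "positive") == \
            asymmetric_bce(p, y, "negative")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            asymmetric_bce(np.zeros((2, 2)), np.zeros((3, 3)), "positive")

    def test_nonnegative_and_zero_iff_match(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
        assert asymmetric_bce(y, y, "negative" if not y.any() else "positive") < 1e-5
        p = rng.uniform(0.05, 0.95, size=(8, 8))
        assert asymmetric_bce(p, y, "positive") > 0


class TestPseudoLabels:
    def test_oracle_pseudolabeler_identity(self):
        # a pseudolabeler that returns the ground-truth rendered map
        kps = [Keypoint(x_px=40, y_px=30), Keypoint(x_px=120, y_px=60)]
        gt = render_targets(kps, (96, 256), OPTICS)

        def oracle(img):
            return Heatmap(values=gt.values, stride=1)

        frames = [np.zeros((96, 256))]
        out = make_pseudo_labels(frames, oracle, OPTICS, threshold=0.5,
                                 stride=1)
        assert np.allclose(out[0].values, gt.values, atol=1e-12)

    def test_empty_frame_gives_zero_target(self):
        def oracle(img):
            return Heatmap(values=np.zeros((96, 256)), stride=1)

        out = make_pseudo_labels([np.zeros((96, 256))], oracle, OPTICS)
        assert not out[0].values.any()

    def test_missing_pseudolabeler_rejected(self):
        with pytest.raises(ValueError):
            make_pseudo_labels([np.zeros((8, 8))], None, OPTICS)

    def test_asymmetric_loss_rescues_label_dropout(self):
        # pseudo-labels missing 20% of cells: training with A=0.1 must
        # reach recall at least as high as A=1 under identical seeds,
        # and strictly higher on this fixture
        def recall_of(a_fp):
            streams = []
            for i in range(3):
                s, _, _ = build_stream(OPTICS, f"pos{i}", "positive",
                                       seed=300 + i, n_frames=40,
                                       label_drop_frac=0.2, drop_seed=i)
                streams.append(s)
            for i in range(2):
                s, _, _ = build_stream(OPTICS, f"neg{i}", "negative",
                                       seed=400 + i, n_frames=40)
                streams.append(s)
            cfg = TrainConfig(epochs=8, batch_size=8, seed=0,
                              loss_weight_A_fp_positive=a_fp)
            model, _ = train_detector(streams, cfg)
            vs, vk, _ = build_stream(OPTICS, "valpos", "positive", seed=555,
                                     n_frames=40)
            tp = fn = 0
            for img, kps in zip(vs.images, vk):
                det = extract_keypoints(predict_heatmap(model, img), 0.5,
                                        OPTICS)
                m = match_detections(det, kps, radius_um=5.6, optics=OPTICS)
                tp += m.true_positives
                fn += m.false_negatives
            return tp / (tp + fn)

        assert recall_of(0.1) > recall_of(1.0)


class _StubModel:
    """Duck-typed detector returning canned heatmaps (for mining tests)."""

    stride = 1

    def __init__(self, max_values):
        self.max_values = list(max_values)
        self.i = 0

    def predict_proba(self, img):
        v = np.zeros((8, 8))
        v[4, 4] = self.max_values[self.i % len(self.max_values)]
        self.i += 1
        return v


class TestMining:
    def test_all_zero_model_retains_nothing(self):
        model = HeatmapNet(seed=0, width=8)   # fresh head bias -4: p≈0.018
        imgs = [np.zeros((32, 32)) for _ in range(5)]
        assert mine_hard_samples(imgs, model, confidence=0.3) == []

    def test_zero_cutoff_retains_everything(self):
        model = HeatmapNet(seed=0, width=8)
        imgs = [np.zeros((32, 32)) for _ in range(4)]
        assert mine_hard_samples(imgs, model, confidence=0.0) == [0, 1, 2, 3]

    def test_known_confidences_cutoff_03(self):
        maxes = [round(0.1 * k, 1) for k in range(1, 11)]   # 0.1 .. 1.0
        stub = _StubModel(maxes)
        imgs = [np.zeros((8, 8))] * 10
        kept = mine_hard_samples(imgs, stub, confidence=0.3)
        assert len(kept) == 8           # brute force: maxes >= 0.3


class TestSessionSampler:
    def test_equal_losses_sample_uniformly(self):
        ledger = SessionLossLedger(losses={"a": 1.0, "b": 1.0})
        draws = session_weighted_sampler(ledger, seed=0, n_draws=10_000)
        f = draws.count("a") / len(draws)
        sigma = math.sqrt(0.25 / 10_000)
        assert abs(f - 0.5) < 3 * sigma

    def test_loss_proportional_frequencies(self):
        ledger = SessionLossLedger(losses={"hard": 2.0, "easy": 1.0})
        draws = session_weighted_sampler(ledger, seed=1, n_draws=10_000)
        f = draws.count("hard") / len(draws)
        p = 2.0 / 3.0
        sigma = math.sqrt(p * (1 - p) / 10_000)
        assert abs(f - p) < 3 * sigma

    def test_single_session_always_drawn(self):
        ledger = SessionLossLedger(losses={"only": 0.7})
        assert set(session_weighted_sampler(ledger, 0, 100)) == {"only"}

    def test_zero_losses_fall_back_to_uniform(self):
        ledger = SessionLossLedger(losses={"a": 0.0, "b": 0.0})
        draws = session_weighted_sampler(ledger, seed=2, n_draws=2_000)
        assert 0.4 < draws.count("a") / 2_000 < 0.6


class TestSplit:
    def test_ten_sessions_split_eight_two(self):
        train, val = split_sessions([f"s{i}" for i in range(10)], 0.8, seed=0)
        assert len(train) == 8 and len(val) == 2

    def test_partition_disjoint_and_exhaustive(self):
        ids = [f"s{i}" for i in range(7)]
        train, val = split_sessions(ids, 0.8, seed=3)
        assert set(train) & set(val) == set()
        assert sorted(train + val) == sorted(ids)

    def test_same_seed_reproduces_partition(self):
        ids = [f"s{i}" for i in range(9)]
        assert split_sessions(ids, 0.8, 5) == split_sessions(ids, 0.8, 5)

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError):
            split_sessions(["only"], 0.8, 0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(n=st.integers(2, 30), seed=st.integers(0, 1000),
           ratio=st.floats(0.5, 0.95))
    def test_split_never_leaks_and_never_empties(self, n, seed, ratio):
        ids = [f"s{i}" for i in range(n)]
        train, val = split_sessions(ids, ratio, seed)
        assert set(train) & set(val) == set()
        assert sorted(train + val) == sorted(ids)
        assert train and val


class TestTrainingLoop:
    def test_lr_schedule_decays_085_per_epoch(self):
        cfg = TrainConfig()
        assert cfg.lr_at(0) == pytest.approx(0.01)
        assert cfg.lr_at(1) == pytest.approx(0.0085)
        assert cfg.lr_at(2) == pytest.approx(0.007225)

    def _tiny_streams(self):
        rng = np.random.default_rng(0)
        imgs_p = [rng.normal(size=(16, 16)) for _ in range(6)]
        tgt = render_targets([Keypoint(x_px=8, y_px=8)], (4, 4), OPTICS,
                             stride=4).values
        imgs_n = [rng.normal(size=(16, 16)) for _ in range(6)]
        return [
            SampleStream("positive", "p0", imgs_p, [tgt] * 6),
            SampleStream("negative", "n0", imgs_n,
                         [np.zeros((4, 4))] * 6),
        ]

    def test_seeded_training_is_deterministic(self):
        cfg = TrainConfig(epochs=2, batch_size=4, seed=9, net_width=8)
        _, m1 = train_detector(self._tiny_streams(), cfg)
        _, m2 = train_detector(self._tiny_streams(), cfg)
        assert m1.mean_loss.tolist() == m2.mean_loss.tolist()

    def test_requires_both_stream_kinds(self):
        streams = self._tiny_streams()[:1]
        with pytest.raises(ValueError):
            train_detector(streams, TrainConfig(epochs=1))

    def test_negative_stream_targets_must_be_zero(self):
        with pytest.raises(ValueError):
            SampleStream("negative", "n0", [np.zeros((8, 8))],
                         [np.ones((2, 2))])

    def test_trained_model_separates_cells_from_background(self, trained,
                                                           fixture_eval):
        # mean heatmap value at true cell centers vs background locations
        at_cells = []
        at_background = []
        rng = np.random.default_rng(0)
        for hm, kps in zip(fixture_eval.heatmaps, fixture_eval.true_kps):
            v = hm.values
            for kp in kps:
                r = int(round((kp.y_px - 1.5) / STRIDE))
                c = int(round((kp.x_px - 1.5) / STRIDE))
                if 0 <= r < v.shape[0] and 0 <= c < v.shape[1]:
                    at_cells.append(v[r, c])
            # background: random cells far from any keypoint
            for _ in range(5):
                r = rng.integers(0, v.shape[0])
                c = rng.integers(0, v.shape[1])
                x_px, y_px = 4 * c + 1.5, 4 * r + 1.5
                if all(math.hypot(x_px - kp.x_px, y_px - kp.y_px) > 30
                       for kp in kps):
                    at_background.append(v[r, c])
        assert np.mean(at_cells) - np.mean(at_background) >= 0.5
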