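"""Training recipe: schedule, split, optimizer steps, reproducibility,
ablation bookkeeping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rrlsrn import (
    LossConfig,
    NetworkConfig,
    PhantomSpec,
    TrainConfig,
    generate_dataset,
    lr_schedule,
    run_ablation,
    split_dataset,
    train,
)
from rrlsrn.training import (
    _apply_overrides,
    adam_step,
    clip_gradients,
    sgd_momentum_step,
)

TINY_NET = NetworkConfig(n_feature_convs=2, channels=4)


def tiny_config(**kw):
    defaults = dict(
        initial_lr=1e-3,
        batch_size=4,
        patch_hr=32,
        epochs=3,
        seed=0,
        optimizer="adam",
        grad_clip=1.0,
        loss=LossConfig(gdl_weight=1e-3),
        network=TINY_NET,
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestSchedule:
    def test_published_halving_schedule(self):
        cfg = TrainConfig()
        assert lr_schedule(0, cfg) == 1e-5
        assert lr_schedule(49, cfg) == 1e-5
        assert lr_schedule(50, cfg) == 5e-6
        assert lr_schedule(100, cfg) == 2.5e-6

    def test_non_increasing(self):
        cfg = TrainConfig()
        rates = [lr_schedule(e, cfg) for e in range(0, 200, 7)]
        assert all(b <= a for a, b in zip(rates[:-1], rates[1:]))

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, TrainConfig())


class TestSplit:
    def test_published_1921_split(self):
        parts = split_dataset(list(range(1921)), (7, 1, 1, 1), seed=0)
        assert [len(p) for p in parts] == [1345, 192, 192, 192]

    def test_exact_ratios(self):
        parts = split_dataset(list(range(10)), (7, 1, 1, 1), seed=3)
        assert [len(p) for p in parts] == [7, 1, 1, 1]

    @given(st.integers(10, 400), st.integers(0, 2**31 - 1))
    def test_partition_property(self, n, seed):
        items = list(range(n))
        parts = split_dataset(items, (7, 1, 1, 1), seed=seed)
        merged = [x for part in parts for x in part]
        assert sorted(merged) == items
        assert sum(len(p) for p in parts) == n

    def test_sizes_deterministic_membership_seeded(self):
        items = list(range(100))
        a = split_dataset(items, (7, 1, 1, 1), seed=1)
        b = split_dataset(items, (7, 1, 1, 1), seed=1)
        c = split_dataset(items, (7, 1, 1, 1), seed=2)
        assert a == b
        assert [len(p) for p in a] == [len(p) for p in c]
        assert a != c

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(5)), (7, 1, 1, 1), seed=0)


class TestOptimizerSteps:
    def test_weight_decay_shrinks_norms_under_zero_gradient(self):
        w = [np.full((4, 4), 2.0), np.full(3, -1.5)]
        grads = [np.zeros_like(x) for x in w]
        vel = [np.zeros_like(x) for x in w]
        before = [np.linalg.norm(x) for x in w]
        for _ in range(3):
            sgd_momentum_step(w, grads, vel, lr=0.1, momentum=0.9, weight_decay=0.01)
        after = [np.linalg.norm(x) for x in w]
        assert all(a < b for a, b in zip(after, before))

    def test_adam_decay_also_shrinks_weights(self):
        w = [np.full((4,), 2.0)]
        g = [np.zeros(4)]
        m = [np.zeros(4)]
        v = [np.zeros(4)]
        before = np.linalg.norm(w[0])
        adam_step(w, g, m, v, t=1, lr=1e-2, beta1=0.9, beta2=0.99, weight_decay=0.01)
        assert np.linalg.norm(w[0]) < before

    def test_momentum_accelerates_constant_gradient(self):
        w = [np.zeros(1)]
        vel = [np.zeros(1)]
        deltas = []
        prev = 0.0
        for _ in range(4):
            sgd_momentum_step(w, [np.ones(1)], vel, 0.1, 0.9, 0.0)
            deltas.append(prev - w[0][0])
            prev = w[0][0]
        assert deltas[1] > deltas[0]  # velocity builds up

    def test_clip_gradients_caps_global_norm(self):
        grads = [np.full((3,), 10.0), np.full((2,), -10.0)]
        clipped = clip_gradients(grads, 1.0)
        total = np.sqrt(sum(float((g * g).sum()) for g in clipped))
        assert total == pytest.approx(1.0, rel=1e-6)
        untouched = clip_gradients([np.full(2, 1e-3)], 1.0)
        assert np.array_equal(untouched[0], np.full(2, 1e-3))


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_dataset(4, PhantomSpec(height=64, width=64, n_ellipses=3), seed=7)


class TestTrain:
    def test_history_bookkeeping(self, tiny_dataset):
        _, hist = train(tiny_dataset, tiny_config())
        assert len(hist) == 3
        assert all(np.isfinite(loss) for loss in hist.loss)

    def test_reproducibility(self, tiny_dataset):
        _, h1 = train(tiny_dataset, tiny_config())
        _, h2 = train(tiny_dataset, tiny_config())
        assert h1.loss == h2.loss

    def test_validation_psnr_recorded(self, tiny_dataset):
        _, hist = train(tiny_dataset[:3], tiny_config(), val_images=tiny_dataset[3:])
        assert all(np.isfinite(v) for v in hist.val_psnr)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], tiny_config())

    def test_undersized_images_rejected(self):
        with pytest.raises(ValueError):
            train([np.zeros((16, 16))], tiny_config())


class TestAblation:
    def test_identical_variant_gives_identical_rows(self):
        data = generate_dataset(
            6, PhantomSpec(height=64, width=64, n_ellipses=3), seed=1
        )
        report = run_ablation(
            data,
            [("a", {}), ("b", {}), ("c", {"loss.gdl_weight": 0.0})],
            tiny_config(),
            n_test=2,
        )
        assert report.row("a", 0) == report.row("b", 0)
        assert len(report.row("a", 0)) == 2
        assert report.variants == ["a", "b", "c"]

    def test_needs_two_variants(self):
        with pytest.raises(ValueError):
            run_ablation([np.zeros((64, 64))], [("only", {})], tiny_config())


def test_apply_overrides_nested():
    cfg = tiny_config()
    out = _apply_overrides(
        cfg, {"loss.gdl_weight": 0.5, "network.use_image_branch": False, "epochs": 7}
    )
    assert out.loss.gdl_weight == 0.5
    assert out.network.use_image_branch is False
    assert out.epochs == 7
    assert out.initial_lr == cfg.initial_lr


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(initial_lr=0.0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="lbfgs")
    with pytest.raises(ValueError):
        TrainConfig(patch_hr=33)
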