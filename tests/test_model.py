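import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taxonet import (
    AugmentPolicy,
    HeadLayout,
    MultilevelClassifier,
    SyntheticSpec,
    TinyConvBackbone,
    TrainConfig,
    build_classifier,
    early_stopper,
    generate_dataset,
    load_checkpoint,
    materialize_image,
    multilevel_loss,
    save_checkpoint,
    softmax,
    train,
)

from conftest import INAT_LEVEL_SIZES


# ---------------------------------------------------------------------------
# softmax
# ---------------------------------------------------------------------------

def test_softmax_uniform_on_equal_logits():
    assert np.allclose(softmax([0.0, 0.0, 0.0]), [1 / 3] * 3)


def test_softmax_closed_form():
    assert np.allclose(softmax([0.0, math.log(2.0)]), [1 / 3, 2 / 3])


def test_softmax_empty_raises():
    with pytest.raises(ValueError):
        softmax([])
    with pytest.raises(ValueError):
        softmax([np.inf, 0.0])


@given(
    st.lists(st.floats(-50, 50), min_size=1, max_size=10),
    st.floats(-100, 100),
)
@settings(deadline=None, max_examples=50)
def test_softmax_normalized_and_shift_invariant(logits, shift):
    z = np.array(logits)
    p = softmax(z)
    assert np.all(p >= 0)
    assert np.isclose(p.sum(), 1.0, atol=1e-9)
    assert np.allclose(softmax(z + shift), p, atol=1e-9)


# ---------------------------------------------------------------------------
# classifier construction
# ---------------------------------------------------------------------------

def test_multilevel_heads_match_published_shape(inat_tree):
    """Seven parallel heads; species head 1010 wide, family head 57."""
    layout = HeadLayout(kind="multilevel", level_sizes=tuple(INAT_LEVEL_SIZES))
    model = build_classifier(TinyConvBackbone(), layout, tree=inat_tree)
    assert len(model.heads.W) == 7
    assert model.heads.W[6].shape[1] == 1010
    assert model.heads.W[4].shape[1] == 57


def test_flat_layout_single_head():
    layout = HeadLayout(kind="flat", level_sizes=tuple(INAT_LEVEL_SIZES))
    model = build_classifier(TinyConvBackbone(), layout)
    assert len(model.heads.W) == 1
    assert model.heads.W[0].shape[1] == 1010


def test_layout_taxonomy_mismatch_raises(branch22_tree):
    layout = HeadLayout(kind="multilevel", level_sizes=(3, 3))
    with pytest.raises(ValueError):
        build_classifier(TinyConvBackbone(), layout, tree=branch22_tree)


def test_forward_probabilities_sum_to_one(rng):
    layout = HeadLayout(kind="multilevel", level_sizes=(2, 4))
    model = build_classifier(TinyConvBackbone(), layout)
    model.heads.W = [rng.normal(size=w.shape) for w in model.heads.W]
    images = rng.uniform(size=(5, 32, 32, 3))
    for probs in model.predict_arrays(images):
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def test_loss_zero_on_perfect_prediction():
    pred = [np.array([0.0, 1.0]), np.array([0.0, 0.0, 1.0, 0.0])]
    assert multilevel_loss(pred, [1, 2]) == pytest.approx(0.0, abs=1e-9)


def test_loss_uniform_closed_form():
    pred = [np.full(2, 0.5), np.full(4, 0.25)]
    assert multilevel_loss(pred, [0, 3]) == pytest.approx(
        math.log(2) + math.log(4)
    )


def test_loss_level_permutation_invariant(rng):
    p1, p2 = softmax(rng.normal(size=3)), softmax(rng.normal(size=5))
    assert multilevel_loss([p1, p2], [1, 4]) == pytest.approx(
        multilevel_loss([p2, p1], [4, 1])
    )


def test_loss_out_of_range_truth_raises():
    with pytest.raises(IndexError):
        multilevel_loss([np.array([1.0, 0.0])], [2])


def test_gradient_step_decreases_loss(rng):
    """One small Adam step on a fixed batch lowers the summed
    cross-entropy."""
    layout = HeadLayout(kind="multilevel", level_sizes=(2, 4))
    model = build_classifier(TinyConvBackbone(), layout)
    feats = rng.normal(size=(8, 64))
    truths = [rng.integers(0, 2, 8), rng.integers(0, 4, 8)]
    from taxonet.model import Adam

    before, grads = model.heads.loss_and_grads(feats, truths)
    Adam(model.heads.params(), lr=1e-3).step(grads)
    after, _ = model.heads.loss_and_grads(feats, truths)
    assert after < before


# ---------------------------------------------------------------------------
# early stopping
# ---------------------------------------------------------------------------

def test_early_stopper_never_halts_on_improvement():
    decision = early_stopper([0.1 * i for i in range(1, 30)], patience=10)
    assert decision.halt_index is None
    assert decision.best_index == 28


def test_early_stopper_constant_trace_halts_after_patience():
    decision = early_stopper([0.5] * 11, patience=10)
    assert decision.halt_index == 10
    assert decision.best_index == 0


def test_early_stopper_best_index_before_decline():
    trace = [0.1, 0.2] + [0.1] * 10
    decision = early_stopper(trace, patience=10)
    assert decision.best_index == 1
    assert decision.halt_index == 11


def test_early_stopper_zero_patience_halts_immediately():
    decision = early_stopper([0.9, 1.0], patience=0)
    assert decision.halt_index == 0
    assert decision.best_index == 0


def test_early_stopper_min_delta_counts_marginal_gains_as_stagnation():
    trace = [0.5, 0.5001, 0.5002, 0.5003]
    assert early_stopper(trace, patience=3, min_delta=0.01).halt_index == 3
    assert early_stopper(trace, patience=3, min_delta=0.0).halt_index is None


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _tiny_config(**kw):
    base = dict(
        learning_rate=0.05, batch_size=8, test_interval_epochs=10,
        patience_tests=10, max_epochs=400, seed=0, resolution=32,
    )
    base.update(kw)
    return TrainConfig(**base)


def _fit(manifest, config, backbone_seed=0, kind="multilevel"):
    tree = manifest.tree
    model = MultilevelClassifier(
        TinyConvBackbone(32, seed=backbone_seed),
        HeadLayout(kind=kind, level_sizes=tuple(tree.level_sizes)),
    )
    return train(model, manifest, tree, config)


def _split_accuracy(result, manifest, split="test"):
    recs = manifest.split_records(split)
    policy = AugmentPolicy(mode="standard")
    images = np.stack(
        [materialize_image(r, policy, 32, manifest.image_root) for r in recs]
    )
    accs = []
    for lvl, probs in enumerate(result.model.predict_arrays(images)):
        y = np.array([r.labels[lvl] for r in recs])
        accs.append(float((np.argmax(probs, axis=1) == y).mean()))
    return accs


def test_train_reaches_perfect_accuracy_on_noiseless_data(noiseless_dataset):
    """The separable 2-level synthetic set is learned exactly at both
    ranks before the early stop fires."""
    result = _fit(noiseless_dataset, _tiny_config())
    coarse, fine = _split_accuracy(result, noiseless_dataset)
    assert coarse == 1.0
    assert fine == 1.0


def test_train_deterministic_given_seed(noiseless_dataset):
    r1 = _fit(noiseless_dataset, _tiny_config(max_epochs=50))
    r2 = _fit(noiseless_dataset, _tiny_config(max_epochs=50))
    assert r1.log == r2.log
    assert r1.monitor_trace == r2.monitor_trace


def test_train_zero_patience_single_evaluation(noiseless_dataset):
    result = _fit(noiseless_dataset, _tiny_config(patience_tests=0))
    assert len(result.monitor_trace) == 1
    assert result.halted_at == 0


def test_train_empty_split_raises(noiseless_dataset):
    from taxonet import DatasetManifest

    only_train = DatasetManifest(
        records=noiseless_dataset.split_records("train"),
        tree=noiseless_dataset.tree,
        image_root=noiseless_dataset.image_root,
    )
    with pytest.raises(ValueError, match="test"):
        _fit(only_train, _tiny_config())


def test_coarse_accuracy_dominates_fine_on_noisy_data(tmp_path):
    """Coarse classes carry more pixels of signal, so coarse test top-1
    stays at or above fine top-1 at every checkpoint (tolerance 0.02,
    three seeds)."""
    margins = []
    for seed in (1, 2, 3):
        spec = SyntheticSpec(
            branching=(2, 2), samples_per_leaf=16, image_size=32,
            noise_sigma=0.4, blur_prob=0.25,
            subject_scale_range=(0.9, 1.0), seed=seed,
        )
        manifest = generate_dataset(spec, 0.75, out_dir=tmp_path / f"n{seed}")
        result = _fit(
            manifest,
            _tiny_config(seed=seed, max_epochs=100, patience_tests=5),
            backbone_seed=seed,
        )
        per_test = {}
        for row in result.log:
            per_test.setdefault(row["test_index"], {})[row["level_name"]] = row["top1"]
        for accs in per_test.values():
            margins.append(accs["level0"] - accs["level1"])
    assert min(margins) >= -0.02


def test_flat_equals_multilevel_on_single_level_taxonomy(tmp_path):
    """With one rank the multilevel model degenerates to the flat one:
    identical training trajectories under the same seed."""
    spec = SyntheticSpec(
        branching=(3,), samples_per_leaf=8, image_size=32,
        noise_sigma=0.0, blur_prob=0.0, subject_scale_range=(1.0, 1.0), seed=4,
    )
    manifest = generate_dataset(spec, 0.75, out_dir=tmp_path / "single")
    cfg = _tiny_config(max_epochs=60)
    flat = _fit(manifest, cfg, kind="flat")
    multi = _fit(manifest, cfg, kind="multilevel")
    assert flat.monitor_trace == multi.monitor_trace
    assert [r["loss"] for r in flat.log] == [r["loss"] for r in multi.log]


def test_checkpoint_roundtrip(noiseless_dataset, tmp_path, rng):
    result = _fit(noiseless_dataset, _tiny_config(max_epochs=30))
    path = tmp_path / "ckpt.zip"
    save_checkpoint(path, result.model, noiseless_dataset.tree, _tiny_config())
    model, tree, config = load_checkpoint(path)
    assert tree == noiseless_dataset.tree
    assert config.learning_rate == 0.05
    images = rng.uniform(size=(3, 32, 32, 3))
    for a, b in zip(model.predict_arrays(images),
                    result.model.predict_arrays(images)):
        assert np.allclose(a, b)
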