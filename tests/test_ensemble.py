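import numpy as np
import pytest

from taxonet import (
    AugmentPolicy,
    DatasetManifest,
    TrainConfig,
    boost_combine,
    boost_combine_arrays,
    build_cascade,
    cascade_predict,
    fit_stacking,
    holdout_split,
    materialize_image,
    measure_member_weights,
    plan_cascade,
    softmax,
    stack_combine,
)


class StubMember:
    """Fixed per-level probability outputs, one row per image."""

    def __init__(self, arrays):
        self.arrays = [np.asarray(a, dtype=float) for a in arrays]

    def predict_arrays(self, images):
        n = len(images)
        return [a[:n] for a in self.arrays]


# ---------------------------------------------------------------------------
# boosting
# ---------------------------------------------------------------------------

def test_boost_single_member_preserves_prediction():
    pred = [np.array([0.6, 0.4]), np.array([0.1, 0.2, 0.7])]
    out = boost_combine([pred], [[0.5, 0.8]])
    for lvl in range(2):
        assert np.allclose(out[lvl], pred[lvl])
        assert np.argmax(out[lvl]) == np.argmax(pred[lvl])


def test_boost_hand_arithmetic():
    """0.5*[0.6,0.4] + 0.9*[0.2,0.8] = [0.48, 0.92] -> class 1."""
    y1, y2 = [np.array([0.6, 0.4])], [np.array([0.2, 0.8])]
    out = boost_combine([y1, y2], [[0.5], [0.9]])
    assert np.allclose(out[0], np.array([0.48, 0.92]) / 1.40)
    assert np.argmax(out[0]) == 1


def test_boost_idempotent_on_identical_members():
    pred = [softmax(np.array([0.3, -1.0, 2.0]))]
    out = boost_combine([pred, pred, pred], [[0.7], [0.7], [0.7]])
    assert np.allclose(out[0], pred[0])


def test_boost_tie_breaks_to_lowest_id():
    """One-hot members on different classes with equal weights give a
    uniform combination over those classes; argmax picks the lowest."""
    a = [np.array([1.0, 0.0, 0.0])]
    b = [np.array([0.0, 0.0, 1.0])]
    out = boost_combine([a, b], [[0.5], [0.5]])
    assert np.allclose(out[0], [0.5, 0.0, 0.5])
    assert np.argmax(out[0]) == 0


def test_boost_matches_brute_force_on_random_inputs(rng):
    members, weights = [], []
    for m in range(3):
        members.append([softmax(rng.normal(size=(10, 4)))]
                       + [softmax(rng.normal(size=(10, 6)))])
        weights.append([float(rng.uniform(0.1, 1.0)) for _ in range(2)])
    combined = boost_combine_arrays(members, weights)
    for lvl in range(2):
        raw = sum(weights[m][lvl] * members[m][lvl] for m in range(3))
        expected = raw / raw.sum(axis=1, keepdims=True)
        assert np.allclose(combined[lvl], expected)
        assert np.allclose(combined[lvl].sum(axis=1), 1.0)


def test_boost_mismatched_levels_raises(rng):
    a = [softmax(rng.normal(size=(4, 3)))]
    b = [softmax(rng.normal(size=(4, 5)))]
    with pytest.raises(ValueError):
        boost_combine_arrays([a, b], [[1.0], [1.0]])


def test_measure_member_weights(rng):
    truth = [[0], [1], [0], [1]]
    right = StubMember([np.eye(2)[[0, 1, 0, 1]]])
    half = StubMember([np.eye(2)[[0, 0, 1, 1]]])
    images = np.zeros((4, 1, 1, 3))
    w = measure_member_weights([right, half], images, truth)
    assert w == [[1.0], [0.5]]


def test_boosting_fixes_disjoint_confident_errors():
    """Two members that err confidently on disjoint thirds of the
    stream: the accuracy-weighted sum corrects every error, so the
    ensemble strictly beats both members."""
    n = 30
    truth = [[i % 2] for i in range(n)]
    rows_a, rows_b = [], []
    for i in range(n):
        right = np.zeros(2)
        right[i % 2] = 0.95
        right[1 - i % 2] = 0.05
        wrong = np.zeros(2)
        wrong[1 - i % 2] = 0.8
        wrong[i % 2] = 0.2
        rows_a.append(wrong if i % 3 == 0 else right)
        rows_b.append(wrong if i % 3 == 1 else right)
    a, b = StubMember([np.array(rows_a)]), StubMember([np.array(rows_b)])
    images = np.zeros((n, 1, 1, 3))
    weights = measure_member_weights([a, b], images, truth)
    combined = boost_combine_arrays(
        [a.predict_arrays(images), b.predict_arrays(images)], weights
    )
    y = np.array([t[0] for t in truth])
    acc = lambda arrays: float((np.argmax(arrays[0], axis=1) == y).mean())
    boosted = acc(combined)
    assert boosted > acc(a.predict_arrays(images))
    assert boosted > acc(b.predict_arrays(images))
    assert boosted == 1.0


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

def test_stacking_identity_init_reproduces_single_member(rng):
    member = [softmax(rng.normal(size=(12, 3))), softmax(rng.normal(size=(12, 5)))]
    stack = fit_stacking(
        [member], [[0, 0]] * 12, (3, 5), epochs=0, init="identity"
    )
    out = stack.combine_arrays([member])
    for lvl in range(2):
        assert np.allclose(out[lvl], member[lvl], atol=1e-6)
    single = stack_combine(stack, [[member[0][0], member[1][0]]])
    assert np.allclose(single[0], member[0][0], atol=1e-6)


def test_stacking_meta_input_width():
    stack = fit_stacking(
        [
            [np.full((4, 2), 0.5), np.full((4, 3), 1 / 3)],
            [np.full((4, 2), 0.5), np.full((4, 3), 1 / 3)],
        ],
        [[0, 0]] * 4,
        (2, 3),
        epochs=0,
    )
    assert stack.in_dim == 2 * (2 + 3)
    assert stack.heads.W[0].shape == (10, 2)


def test_stacking_learns_to_trust_the_reliable_member(rng):
    """Member 2 always right, member 1 always wrong on a 2-class
    stream: the trained meta-layer is at least as accurate as member 2
    (within 0.02)."""
    n = 120
    y = rng.integers(0, 2, size=n)
    right = np.eye(2)[y] * 0.9 + 0.05
    wrong = np.eye(2)[1 - y] * 0.9 + 0.05
    stack = fit_stacking(
        [[wrong], [right]],
        [[int(v)] for v in y],
        (2,),
        config=TrainConfig(learning_rate=0.05, batch_size=16, seed=0),
        epochs=100,
    )
    out = stack.combine_arrays([[wrong], [right]])
    acc = float((np.argmax(out[0], axis=1) == y).mean())
    assert acc >= 1.0 - 0.02


def test_stacking_mismatched_members_raise():
    with pytest.raises(ValueError):
        fit_stacking(
            [[np.full((4, 2), 0.5)], [np.full((4, 3), 1 / 3)]],
            [[0]] * 4,
            (2,),
            epochs=0,
        )


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def test_plan_cascade_published_arity(inat_tree):
    """Routing at the phylum rank (4 categories) yields 4 specialists."""
    spec = plan_cascade(inat_tree, routing_level=1)
    assert spec.n_specialists == 4
    # each specialist's label spaces partition the finer ranks
    for lvl_offset in range(5):
        total = sum(len(ids[lvl_offset]) for ids in spec.subtree_ids.values())
        assert total == inat_tree.level_sizes[2 + lvl_offset]


def test_plan_cascade_coarse_fill(inat_tree):
    spec = plan_cascade(inat_tree, routing_level=1)
    for cat, path in spec.coarse_path.items():
        assert path[1] == cat
        assert path[0] == inat_tree.parent[1][cat]


def _built_cascade(noiseless_dataset):
    config = TrainConfig(
        learning_rate=0.05, batch_size=8, test_interval_epochs=10,
        patience_tests=8, max_epochs=300, seed=0, resolution=32,
    )
    return build_cascade(noiseless_dataset, noiseless_dataset.tree, 0, config)


def _test_images(manifest):
    recs = manifest.split_records("test")
    policy = AugmentPolicy(mode="standard")
    images = np.stack(
        [materialize_image(r, policy, 32, manifest.image_root) for r in recs]
    )
    return images, recs


def test_cascade_perfect_on_noiseless_data(noiseless_dataset):
    """Perfect router composed with perfect specialists gives perfect
    finest-rank accuracy."""
    spec = _built_cascade(noiseless_dataset)
    assert spec.n_specialists == 2
    images, recs = _test_images(noiseless_dataset)
    preds = cascade_predict(spec, images)
    fine = np.array([np.argmax(p[-1]) for p in preds])
    truth = np.array([r.labels[-1] for r in recs])
    assert (fine == truth).all()
    for p in preds:
        assert np.isclose(p[0].sum(), 1.0)
        assert np.isclose(p[1].sum(), 1.0)


def test_cascade_support_restriction(noiseless_dataset):
    """A router forced to one category confines all finest-rank mass to
    that category's subtree."""
    spec = _built_cascade(noiseless_dataset)
    images, _ = _test_images(noiseless_dataset)
    n = len(images)
    spec.router = StubMember([np.tile([1.0, 0.0], (n, 1))])
    preds = cascade_predict(spec, images)
    subtree = spec.subtree_ids[0][0]  # leaves under coarse category 0
    outside = [i for i in range(4) if i not in subtree]
    for p in preds:
        assert np.all(p[1][outside] == 0.0)
        assert np.argmax(p[0]) == 0


def test_cascade_error_propagation_equals_routing_accuracy(noiseless_dataset):
    """With perfect specialists, finest-rank accuracy equals router
    accuracy exactly: forced routing mistakes each cost the sample."""
    spec = _built_cascade(noiseless_dataset)
    images, recs = _test_images(noiseless_dataset)
    y0 = np.array([r.labels[0] for r in recs])
    routed = y0.copy()
    routed[:2] = 1 - routed[:2]  # force two mistakes
    spec.router = StubMember([np.eye(2)[routed]])
    preds = cascade_predict(spec, images)
    fine = np.array([np.argmax(p[-1]) for p in preds])
    truth = np.array([r.labels[-1] for r in recs])
    routing_acc = float((routed == y0).mean())
    assert float((fine == truth).mean()) == routing_acc


def test_cascade_missing_category_raises(noiseless_dataset):
    tree = noiseless_dataset.tree
    only_cat0 = DatasetManifest(
        records=[
            r for r in noiseless_dataset.records
            if r.labels[0] == 0 or r.split == "test"
        ],
        tree=tree,
        image_root=noiseless_dataset.image_root,
    )
    with pytest.raises(ValueError, match=tree.name_of(0, 1)):
        build_cascade(only_cat0, tree, 0, TrainConfig(learning_rate=0.05))


def test_holdout_split_stratified(noiseless_dataset):
    reduced, holdout = holdout_split(noiseless_dataset, fraction=0.25, seed=1)
    assert len(holdout) > 0
    assert all(r.split == "train" for r in holdout)
    assert len(reduced.records) + len(holdout) == len(noiseless_dataset.records)
    # every leaf still represented in the reduced train split
    assert (reduced.class_counts > 0).all()
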