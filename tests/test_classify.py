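import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octdme.classify import (
    ClassifierSpec,
    EvalReport,
    FeatureBlock,
    enumerate_ltpo_folds,
    evaluate_pipeline,
    majority_vote,
    train_bscan_classifier,
)
from octdme.io import DatasetManifest, Label


def _manifest(n_dme, n_normal):
    entries = [(f"d{i}.tiff", f"d{i}", Label.DME) for i in range(n_dme)]
    entries += [(f"n{i}.tiff", f"n{i}", Label.NORMAL) for i in range(n_normal)]
    return DatasetManifest(entries)


def _blob_store(manifest, rng, n_scans=8, dim=4, sep=6.0):
    """Well-separated per-class Gaussian B-scan vectors."""
    store = {}
    for _, pid, lab in manifest.entries:
        mu = sep if lab == Label.DME else 0.0
        store[pid] = mu + rng.standard_normal((n_scans, dim))
    return store


def test_sixteen_plus_sixteen_gives_sixteen_folds():
    folds = enumerate_ltpo_folds(_manifest(16, 16))
    assert len(folds) == 16
    for f in folds:
        assert len(f.train_ids) == 30
        assert f.held_out[0].startswith("d") and f.held_out[1].startswith("n")


def test_two_plus_two_folds():
    folds = enumerate_ltpo_folds(_manifest(2, 2))
    assert len(folds) == 2 and all(len(f.train_ids) == 2 for f in folds)


def test_unbalanced_manifest_rejected():
    with pytest.raises(ValueError):
        enumerate_ltpo_folds(_manifest(3, 2))


def test_majority_vote_rules():
    assert majority_vote(np.r_[np.ones(70), np.zeros(58)]) == (Label.DME, 70)
    assert majority_vote(np.r_[np.ones(64), np.zeros(64)]) == (Label.DME, 64)  # tie -> DME
    assert majority_vote(np.zeros(128)) == (Label.NORMAL, 0)
    with pytest.raises(ValueError):
        majority_vote(np.array([]))


@settings(derandomize=True, max_examples=50)
@given(st.integers(1, 200), st.integers(0, 200))
def test_majority_vote_threshold_property(n_total, n_diseased):
    n_diseased = min(n_diseased, n_total)
    preds = np.r_[np.ones(n_diseased), np.zeros(n_total - n_diseased)]
    label, count = majority_vote(preds)
    assert count == n_diseased
    assert (label == Label.DME) == (2 * n_diseased >= n_total)


def test_se_sp_arithmetic():
    """Confusion counts (14, 2, 14, 2) map to SE = SP = 87.5%."""
    r = EvalReport(tp=14, fn=2, tn=14, fp=2)
    assert r.sensitivity == pytest.approx(0.875)
    assert r.specificity == pytest.approx(0.875)


def test_linear_svm_separable_blobs(rng):
    X = np.vstack([rng.standard_normal((20, 2)), 8 + rng.standard_normal((20, 2))])
    y = np.r_[np.zeros(20), np.ones(20)]
    clf = train_bscan_classifier(ClassifierSpec("linear_svm"), X, y)
    assert (clf.predict(X) == y).all()
    clf2 = train_bscan_classifier(ClassifierSpec("linear_svm"), X, y)
    np.testing.assert_array_equal(clf.predict(X), clf2.predict(X))


def test_single_class_training_rejected(rng):
    with pytest.raises(ValueError):
        train_bscan_classifier(ClassifierSpec("rf"), rng.random((10, 2)), np.zeros(10))


def test_rf_accuracy_grows_with_trees(rng):
    """Held-out accuracy is non-decreasing in expectation with more trees."""
    accs = {n: [] for n in (1, 100)}
    for seed in range(10):
        r = np.random.default_rng(seed)
        X = np.vstack([r.standard_normal((60, 5)), 1.0 + r.standard_normal((60, 5))])
        y = np.r_[np.zeros(60), np.ones(60)]
        Xt = np.vstack([r.standard_normal((40, 5)), 1.0 + r.standard_normal((40, 5))])
        yt = np.r_[np.zeros(40), np.ones(40)]
        for n in accs:
            clf = train_bscan_classifier(ClassifierSpec("rf", n_trees=n, seed=seed), X, y)
            accs[n].append((clf.predict(Xt) == yt).mean())
    assert np.mean(accs[100]) >= np.mean(accs[1])


@pytest.mark.parametrize("representation", ["hist", "hist_pca", "hist_pca_bow"])
def test_perfect_pipeline_on_separable_volumes(representation, rng):
    """Well-separated synthetic volumes give SE = SP = 100% in every representation."""
    manifest = _manifest(4, 4)
    store = _blob_store(manifest, rng, n_scans=10)
    block = FeatureBlock(store, pca_components=2)
    report = evaluate_pipeline(
        [block], manifest, representation=representation, n_words=2, seed=0
    )
    assert report.sensitivity == 1.0 and report.specificity == 1.0
    assert report.tp + report.fn == 4 and report.tn + report.fp == 4


def test_all_dme_predictor_se_sp():
    """A degenerate always-DME decision gives SE = 100%, SP = 0%."""
    r = EvalReport(tp=8, fn=0, tn=0, fp=8)
    assert r.sensitivity == 1.0 and r.specificity == 0.0


def test_confusion_partitions_volumes(rng):
    manifest = _manifest(3, 3)
    store = _blob_store(manifest, rng, sep=0.1)  # barely separated: arbitrary outcomes
    report = evaluate_pipeline([FeatureBlock(store, 2)], manifest, seed=0)
    assert report.tp + report.fn == 3 and report.tn + report.fp == 3


def test_no_leak_from_held_out_volumes(rng):
    """Deleting held-out features leaves every fold's predictions unchanged."""
    manifest = _manifest(3, 3)
    store = _blob_store(manifest, rng, sep=1.0)
    full = evaluate_pipeline([FeatureBlock(dict(store), 2)], manifest, seed=0)
    # corrupt each fold's held-out volumes wildly; train-side behavior must not change
    for fold_idx, fold in enumerate(enumerate_ltpo_folds(manifest)):
        corrupted = {
            pid: (vec + 1e6 if pid in fold.held_out else vec) for pid, vec in store.items()
        }
        # evaluating only this fold's training patients: build a reduced manifest
        reduced = DatasetManifest(
            [e for e in manifest.entries if e[1] in fold.train_ids]
        )
        r1 = evaluate_pipeline([FeatureBlock({p: store[p] for p in fold.train_ids}, 2)], reduced, seed=0)
        r2 = evaluate_pipeline(
            [FeatureBlock({p: corrupted[p] for p in fold.train_ids}, 2)], reduced, seed=0
        )
        assert [f.predicted for f in r1.folds] == [f.predicted for f in r2.folds]


def test_combined_blocks_concatenate_pca_dims(rng):
    """Two descriptor blocks reduce independently and concatenate (e.g. 40 + 20)."""
    manifest = _manifest(2, 2)
    s1 = _blob_store(manifest, rng, dim=50)
    s2 = _blob_store(manifest, rng, dim=30)
    from octdme.classify import _fit_fold_representation, _patient_matrix

    blocks = [FeatureBlock(s1, 3), FeatureBlock(s2, 2)]
    models = _fit_fold_representation(blocks, [p for _, p, _ in manifest.entries], seed=0)
    mat = _patient_matrix(blocks, models, "d0")
    assert mat.shape == (8, 5)


def test_evaluation_deterministic(rng):
    manifest = _manifest(3, 3)
    store = _blob_store(manifest, rng, sep=0.5)
    r1 = evaluate_pipeline([FeatureBlock(store, 2)], manifest, seed=0)
    r2 = evaluate_pipeline([FeatureBlock(store, 2)], manifest, seed=0)
    assert (r1.tp, r1.fn, r1.tn, r1.fp) == (r2.tp, r2.fn, r2.tn, r2.fp)


def test_missing_features_named(rng):
    manifest = _manifest(2, 2)
    store = _blob_store(manifest, rng)
    del store["n1"]
    with pytest.raises(ValueError, match="n1"):
        evaluate_pipeline([FeatureBlock(store, 2)], manifest)


def test_experiment_grid_shapes(rng):
    from octdme.classify import experiment_grid

    manifest = _manifest(3, 3)
    stores = {
        "lbp16": _blob_store(manifest, rng, dim=6),
        "hog": _blob_store(manifest, rng, dim=8),
    }
    grid = experiment_grid(
        stores,
        manifest,
        classifiers=[ClassifierSpec("linear_svm")],
        word_counts=(2, 3),
        pca_components={"lbp16": 2, "hog": 2},
        combine_pairs=[("hog", "lbp16")],
    )
    # 2 stores x (hist + hist_pca) + 1 combined + 2 stores x 2 word counts = 9 rows
    assert len(grid) == 9
    assert set(grid.representation) == {"hist", "hist_pca", "hist_pca_bow"}
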