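"""Classifiers, majority voting, leave-two-patients-out CV and SE/SP reporting.

B-scans inherit their volume's label for training (ground truth exists
only at the volume level).  Volume decisions use the majority-vote rule
over per-B-scan predictions for the Histogram and Histogram+PCA
representations; bag-of-words volume histograms are classified
directly.  Evaluation holds out one DME and one normal patient per
fold and accumulates a volume-level confusion matrix over all folds,
reported as sensitivity TP/(TP+FN) and specificity TN/(TN+FP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import DatasetManifest, Label
from .represent import BagOfWords, HistogramPCA

logger = logging.getLogger(__name__)

DISEASED = 1
HEALTHY = 0


@dataclass
class ClassifierSpec:
    """Classifier family and hyperparameters."""

    kind: str = "linear_svm"  # linear_svm | rbf_svm | rf
    C: float = 1.0
    gamma: float | str = "auto"  # rbf: 'auto' = 1 / n_features
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("linear_svm", "rbf_svm", "rf"):
            raise ValueError(f"unknown classifier {self.kind!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def build(self):
        """Fresh unfitted estimator; SVMs get train-fold standardization."""
        if self.kind == "linear_svm":
            clf = SVC(kernel="linear", C=self.C, random_state=self.seed)
        elif self.kind == "rbf_svm":
            clf = SVC(kernel="rbf", C=self.C, gamma=self.gamma, random_state=self.seed)
        else:
            return RandomForestClassifier(n_estimators=self.n_trees, random_state=self.seed)
        return Pipeline([("scale", StandardScaler()), ("svm", clf)])


def train_bscan_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray):
    """Fit a B-scan-level classifier on labeled training vectors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    return spec.build().fit(X, y)


def majority_vote(predictions: np.ndarray) -> tuple[Label, int]:
    """Volume decision from per-B-scan predictions (1 = diseased).

    DME iff the diseased count is at least half the B-scans; exact
    ties (count == n/2) classify as DME, favoring sensitivity.
    """
    predictions = np.asarray(predictions)
    n = predictions.size
    if n == 0:
        raise ValueError("majority_vote needs at least one prediction")
    diseased = int((predictions == DISEASED).sum())
    label = Label.DME if 2 * diseased >= n else Label.NORMAL
    return label, diseased


@dataclass
class FoldResult:
    """One leave-two-patients-out fold: held-out pair and its predictions."""

    held_out: tuple[str, str]  # (DME patient, normal patient)
    train_ids: list[str]
    predicted: dict[str, Label] = field(default_factory=dict)
    diseased_counts: dict[str, int] = field(default_factory=dict)


def enumerate_ltpo_folds(manifest: DatasetManifest) -> list[FoldResult]:
    """Pair the i-th DME with the i-th normal patient (manifest order).

    Requires a balanced manifest; n patients per class give n folds.
    """
    dme = [pid for _, pid, lab in manifest.entries if lab == Label.DME]
    normal = [pid for _, pid, lab in manifest.entries if lab == Label.NORMAL]
    if len(dme) != len(normal):
        raise ValueError(
            f"leave-two-patients-out needs balanced classes, got {len(dme)} DME vs {len(normal)} normal"
        )
    if not dme:
        raise ValueError("manifest is empty")
    all_ids = manifest.patient_ids
    folds = []
    for d, n in zip(dme, normal):
        folds.append(FoldResult(held_out=(d, n), train_ids=[p for p in all_ids if p not in (d, n)]))
    return folds


@dataclass
class EvalReport:
    """Volume-level confusion counts over all folds plus the config snapshot."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0
    folds: list[FoldResult] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


@dataclass
class FeatureBlock:
    """Per-patient B-scan descriptor matrices plus an optional PCA width.

    ``vectors`` maps patient_id -> (n_scans, D).  ``pca_components``
    None means the raw histograms are used (Histogram representation);
    an int selects Histogram+PCA.  Multiple blocks are PCA-reduced
    independently and concatenated (e.g. HoG^PCA + LBP^PCA).
    """

    vectors: dict[str, np.ndarray]
    pca_components: int | None = 20


def _fit_fold_representation(
    blocks: list[FeatureBlock], train_ids: list[str], seed: int
) -> list[HistogramPCA | None]:
    models: list[HistogramPCA | None] = []
    for blk in blocks:
        if blk.pca_components is None:
            models.append(None)
        else:
            train = np.vstack([blk.vectors[p] for p in train_ids])
            n = blk.pca_components
            if n >= train.shape[0]:  # desk-scale folds: clamp, warn
                n = train.shape[0] - 1
                logger.warning("PCA components clamped to n_train - 1 = %d", n)
            models.append(HistogramPCA(n_components=n, seed=seed).fit(train))
    return models


def _patient_matrix(
    blocks: list[FeatureBlock], models: list[HistogramPCA | None], pid: str
) -> np.ndarray:
    parts = []
    for blk, model in zip(blocks, models):
        v = blk.vectors[pid]
        parts.append(v if model is None else model.transform(v))
    return np.hstack(parts)


def evaluate_pipeline(
    blocks: list[FeatureBlock] | FeatureBlock,
    manifest: DatasetManifest,
    representation: str = "hist_pca",
    classifier: ClassifierSpec | None = None,
    n_words: int = 30,
    seed: int = 0,
) -> EvalReport:
    """Leave-two-patients-out evaluation of one pipeline configuration.

    Per fold, the representation (PCA and, for the bag-of-words mode,
    the codebook) and the classifier are fitted on training patients
    only.  Histogram and Histogram+PCA classify individual B-scans and
    aggregate by majority vote; Histogram+PCA+BoW classifies the
    per-volume word histograms directly.
    """
    if isinstance(blocks, FeatureBlock):
        blocks = [blocks]
    if representation not in ("hist", "hist_pca", "hist_pca_bow"):
        raise ValueError(f"unknown representation {representation!r}")
    if representation == "hist":
        blocks = [FeatureBlock(b.vectors, None) for b in blocks]
    if classifier is None:
        classifier = ClassifierSpec(seed=seed)
    labels = {pid: lab for _, pid, lab in manifest.entries}
    missing = [pid for pid in labels if any(pid not in b.vectors for b in blocks)]
    if missing:
        raise ValueError(f"missing features for volumes: {missing}")

    report = EvalReport(
        config={
            "representation": representation,
            "classifier": classifier.kind,
            "n_words": n_words if representation == "hist_pca_bow" else None,
        }
    )
    for fold in enumerate_ltpo_folds(manifest):
        models = _fit_fold_representation(blocks, fold.train_ids, seed)
        train_mats = {p: _patient_matrix(blocks, models, p) for p in fold.train_ids}
        test_mats = {p: _patient_matrix(blocks, models, p) for p in fold.held_out}

        if representation == "hist_pca_bow":
            bow = BagOfWords(n_words=n_words, seed=seed).fit(np.vstack(list(train_mats.values())))
            Xtr = bow.transform([train_mats[p] for p in fold.train_ids])
            ytr = np.array([DISEASED if labels[p] == Label.DME else HEALTHY for p in fold.train_ids])
            clf = train_bscan_classifier(classifier, Xtr, ytr)
            for pid in fold.held_out:
                pred = clf.predict(bow.encode(test_mats[pid])[None])[0]
                fold.predicted[pid] = Label.DME if pred == DISEASED else Label.NORMAL
        else:
            Xtr = np.vstack([train_mats[p] for p in fold.train_ids])
            ytr = np.concatenate(
                [
                    np.full(
                        train_mats[p].shape[0],
                        DISEASED if labels[p] == Label.DME else HEALTHY,
                    )
                    for p in fold.train_ids
                ]
            )
            clf = train_bscan_classifier(classifier, Xtr, ytr)
            for pid in fold.held_out:
                preds = clf.predict(test_mats[pid])
                lab, count = majority_vote(preds)
                fold.predicted[pid] = lab
                fold.diseased_counts[pid] = count

        for pid in fold.held_out:
            truth, pred = labels[pid], fold.predicted[pid]
            if truth == Label.DME:
                report.tp += pred == Label.DME
                report.fn += pred != Label.DME
            else:
                report.tn += pred == Label.NORMAL
                report.fp += pred != Label.NORMAL
        report.folds.append(fold)
    return report


def experiment_grid(
    feature_stores: dict[str, dict[str, np.ndarray]],
    manifest: DatasetManifest,
    classifiers: list[ClassifierSpec] | None = None,
    word_counts: tuple[int, ...] = (10, 30, 40, 50),
    pca_components: dict[str, int] | None = None,
    combine_pairs: list[tuple[str, str]] | None = None,
    seed: int = 0,
    run_bow: bool = True,
) -> pd.DataFrame:
    """Run the two experiment families over a grid of configurations.

    Family 1 evaluates Histogram and Histogram+PCA for each individual
    descriptor store and for each combined pair (both members
    PCA-reduced then concatenated).  Family 2 evaluates
    Histogram+PCA+BoW across ``word_counts``.  Returns one row per
    (descriptor, representation, classifier[, words]) with SE/SP and
    confusion counts.
    """
    if classifiers is None:
        classifiers = [
            ClassifierSpec("linear_svm", seed=seed),
            ClassifierSpec("rbf_svm", seed=seed),
            ClassifierSpec("rf", seed=seed),
        ]
    if pca_components is None:
        pca_components = {}

    def _ncomp(name: str) -> int:
        if name in pca_components:
            return pca_components[name]
        return 40 if "hog" in name.lower() else 20

    configs: list[tuple[str, str, list[FeatureBlock], int | None]] = []
    for name, store in feature_stores.items():
        configs.append((name, "hist", [FeatureBlock(store, None)], None))
        configs.append((name, "hist_pca", [FeatureBlock(store, _ncomp(name))], None))
    for a, b in combine_pairs or []:
        blocks = [
            FeatureBlock(feature_stores[a], _ncomp(a)),
            FeatureBlock(feature_stores[b], _ncomp(b)),
        ]
        configs.append((f"{a}+{b}", "hist_pca", blocks, None))
    if run_bow:
        for name, store in feature_stores.items():
            for w in word_counts:
                configs.append((name, "hist_pca_bow", [FeatureBlock(store, _ncomp(name))], w))

    rows = []
    for name, rep, blocks, words in configs:
        for spec in classifiers:
            rep_kwargs = {"n_words": words} if words else {}
            r = evaluate_pipeline(blocks, manifest, representation=rep, classifier=spec, seed=seed, **rep_kwargs)
            rows.append(
                {
                    "descriptor": name,
                    "representation": rep,
                    "classifier": spec.kind,
                    "n_words": words,
                    "SE": r.sensitivity,
                    "SP": r.specificity,
                    "TP": r.tp,
                    "FN": r.fn,
                    "TN": r.tn,
                    "FP": r.fp,
                }
            )
    return pd.DataFrame(rows)
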