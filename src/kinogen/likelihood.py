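"""Random-Forest kinase-inhibition-likelihood classifiers and their evaluation.

Two classifier modes over two predictor spaces: a binary model separating one
target family (SRC by default) from everything else, and a multiclass model
assigning each kinase family its own label; predictors are either the
20-feature chemical descriptor vector or the raw latent coordinates
(d + 1 = 197 table columns at the default latent dimensionality).  The
forest's averaged tree vote is read as the probability that a molecule is a
kinase-inhibitor-like compound, and molecules scoring strictly above the
likelihood threshold are designated target-family-like.

Evaluation covers accuracy, precision, recall, F1, the ROC curve
(sensitivity against 1 - specificity) with trapezoidal AUC, the
precision-recall curve, and impurity-based feature importances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import train_test_split

from .molecules import DESCRIPTOR_NAMES, Family, MoleculeRecord, descriptor_table


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one likelihood classifier."""

    mode: str = "binary"  # "binary" or "multiclass"
    space: str = "feature"  # "feature" (20 descriptors) or "latent" (d dims)
    n_trees: int = 500
    seed: int = 0
    positive_class: Family = Family.SRC
    class_weight: str | None = None  # None (unweighted) or "balanced"

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "multiclass"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.space not in ("feature", "latent"):
            raise ValueError(f"unknown space {self.space!r}")


def build_training_table(
    labeled_sets: Mapping[Family, Sequence[MoleculeRecord]],
    spec: ClassifierSpec,
    latents: Mapping[Family, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble the predictors + ``target`` table for a classifier spec.

    Binary mode assigns 1 to the positive family and 0 to every other set
    (other kinase families and the background molecules together);
    multiclass assigns each family a distinct integer code.  Latent-space
    specs require a latent matrix per family, aligned with the records.
    """
    frames = []
    class_codes = {fam: i for i, fam in enumerate(sorted(labeled_sets, key=lambda f: f.value))}
    for fam, recs in labeled_sets.items():
        recs = list(recs)
        if not recs:
            raise ValueError(f"family {fam.value} has zero members")
        if spec.space == "feature":
            block = descriptor_table(recs)
        else:
            if latents is None or fam not in latents:
                raise ValueError(f"latent-space spec needs a latent matrix for {fam.value}")
            z = np.asarray(latents[fam], dtype=float)
            if z.shape[0] != len(recs):
                raise ValueError(f"latent rows misaligned with records for {fam.value}")
            block = pd.DataFrame(
                z, index=[r.id for r in recs], columns=[f"z{j}" for j in range(z.shape[1])]
            )
        if spec.mode == "binary":
            block["target"] = int(fam == spec.positive_class)
        else:
            block["target"] = class_codes[fam]
        frames.append(block)
    return pd.concat(frames, axis=0)


def train(table: pd.DataFrame, spec: ClassifierSpec) -> RandomForestClassifier:
    """Fit a seeded Random Forest on a predictors + ``target`` table.

    Hyperparameters: ``n_trees`` trees, unlimited depth, sqrt(p) features per
    split.  The predicted probability is the mean of the per-tree class
    votes, normalised per row in the multiclass case.  Raw (unstandardised)
    predictor values are used throughout; the forest is scale-invariant.
    """
    y = table["target"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain at least 2 classes")
    X = table.drop(columns="target").to_numpy(dtype=float)
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features="sqrt",
        random_state=spec.seed,
        class_weight=spec.class_weight,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def predict_likelihood(model: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    """Probability of the positive (or per-sample argmax-free positive-class)
    label for a batch of predictor rows; values in [0, 1]."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_features_in_:
        raise ValueError(
            f"predictor dimensionality {x.shape[1]} != model expectation {model.n_features_in_}"
        )
    proba = model.predict_proba(x)
    if proba.shape[1] == 2:
        pos_col = int(np.where(model.classes_ == model.classes_.max())[0][0])
        return proba[:, pos_col]
    return proba.max(axis=1)


def split_table(
    table: pd.DataFrame, test_size: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split on the ``target`` column."""
    train_df, test_df = train_test_split(
        table, test_size=test_size, random_state=seed, stratify=table["target"]
    )
    return train_df, test_df


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def binary_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from a binary confusion matrix.

    An undefined ratio (empty denominator) is reported as NaN with a warning
    rather than silently as 0.
    """
    import warnings

    acc = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp == 0:
        warnings.warn("no positive predictions: precision undefined")
        prec = float("nan")
    else:
        prec = cm.tp / (cm.tp + cm.fp)
    if cm.tp + cm.fn == 0:
        warnings.warn("no positive labels: recall undefined")
        rec = float("nan")
    else:
        rec = cm.tp / (cm.tp + cm.fn)
    if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
        f1 = float("nan")
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc_points: np.ndarray  # columns: 1 - specificity, sensitivity
    pr_points: np.ndarray  # columns: recall, precision
    feature_importances: list[tuple[str, float]]  # descending weight, sums to 1


def evaluate(
    model: RandomForestClassifier,
    test_table: pd.DataFrame,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Score a fitted binary model on a held-out table.

    The test table must be disjoint from the training fold.  The decision
    label is positive when the likelihood is strictly greater than the
    threshold; curve-based metrics (ROC, AUC, PR) use the raw scores.
    """
    y = test_table["target"].to_numpy()
    X = test_table.drop(columns="target")
    scores = predict_likelihood(model, X.to_numpy(dtype=float))
    pred = (scores > threshold).astype(int)
    cm = ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
    )
    metrics = binary_metrics(cm)
    fpr, tpr, _ = roc_curve(y, scores)
    prec_c, rec_c, _ = precision_recall_curve(y, scores)
    importances = model.feature_importances_
    ranked = sorted(zip(X.columns, importances), key=lambda t: -t[1])
    return EvaluationReport(
        confusion=cm,
        accuracy=metrics["accuracy"],
        precision=metrics["precision"],
        recall=metrics["recall"],
        f1=metrics["f1"],
        auc=float(_trapezoid_auc(fpr, tpr)),
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([rec_c, prec_c]),
        feature_importances=[(str(n), float(w)) for n, w in ranked],
    )


def auc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the probability that a random positive outscores a random
    negative (ties count half).  O(n_pos * n_neg) enumeration; intended as an
    independent cross-check on small tables."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes for AUC")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def plot_roc_pr(report: EvaluationReport, roc_path: str, pr_path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.roc_points[:, 0], report.roc_points[:, 1])
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC (AUC = {report.auc:.3f})")
    fig.tight_layout()
    fig.savefig(roc_path, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.pr_points[:, 0], report.pr_points[:, 1])
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_title("Precision-recall")
    fig.tight_layout()
    fig.savefig(pr_path, dpi=120)
    plt.close(fig)
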