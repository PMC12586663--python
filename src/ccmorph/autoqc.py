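"""Automated pass/fail quality control of CC segmentations.

Shape records (areas, thicknesses, length, perimeter, curvature) feed a
majority-voting ensemble of five classifiers — gradient-boosted trees
(XGBoost), k-nearest neighbors, a support-vector classifier, logistic
regression, and a random forest — that labels each segmentation Pass or
Fail.  Two optional neural members (a 42-22-11 multilayer perceptron
and a wide 80-80-80-40-40-40 one) can be switched on; ties, possible
only with an even member count, break toward Fail (ambiguous
segmentations should be reviewed, not trusted).

Features are standardized with statistics of the training split only;
missing metrics (e.g. regions absent from a broken mask) are imputed to
0 with a paired missingness indicator so "absent" stays distinguishable
from "small".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .morphometry import ShapeRecord

#: Label conventions: QC's positive class is a failed segmentation.
PASS, FAIL = "pass", "fail"

DEFAULT_MEMBERS = ("xgboost", "knn", "svc", "logistic", "random_forest")
NEURAL_MEMBERS = ("mlp_42_22_11", "mlp_wide_deep")


def _make_member(name: str, seed: int):
    if name == "xgboost":
        return XGBClassifier(
            n_estimators=100, random_state=seed, eval_metric="logloss", verbosity=0
        )
    if name == "knn":
        return KNeighborsClassifier()
    if name == "svc":
        return SVC(random_state=seed)
    if name == "logistic":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "mlp_42_22_11":
        return MLPClassifier(
            hidden_layer_sizes=(42, 22, 11), max_iter=2000, random_state=seed
        )
    if name == "mlp_wide_deep":
        return MLPClassifier(
            hidden_layer_sizes=(80, 80, 80, 40, 40, 40), max_iter=2000, random_state=seed
        )
    raise ValueError(f"unknown QC member {name!r}")


def records_to_features(records: list[ShapeRecord]) -> np.ndarray:
    """Feature matrix: the 15 shape metrics, NaN->0 plus indicators."""
    raw = np.stack([r.metric_values() for r in records])
    missing = ~np.isfinite(raw)
    filled = np.where(missing, 0.0, raw)
    return np.hstack([filled, missing.astype(float)])


@dataclass
class QCModelBundle:
    """Fitted ensemble members plus scaling and split metadata."""

    members: dict
    feature_mean: np.ndarray
    feature_std: np.ndarray
    member_names: tuple[str, ...]
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray

    def _transform(self, records: list[ShapeRecord]) -> np.ndarray:
        x = records_to_features(records)
        return (x - self.feature_mean) / self.feature_std

    def vote_matrix(self, records: list[ShapeRecord]) -> np.ndarray:
        """Per-member fail votes, shape (n_records, n_members), in {0,1}."""
        x = self._transform(records)
        return np.stack(
            [self.members[name].predict(x) for name in self.member_names], axis=1
        )

    def fail_scores(self, records: list[ShapeRecord]) -> np.ndarray:
        """Fraction of members voting fail: the ranking score for AUC."""
        return self.vote_matrix(records).mean(axis=1)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "member_names": list(self.member_names),
            "seed": self.seed,
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for name, model in self.members.items():
            joblib.dump(model, directory / f"{name}.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "QCModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        names = tuple(manifest["member_names"])
        members = {n: joblib.load(directory / f"{n}.joblib") for n in names}
        return cls(
            members,
            np.array(manifest["feature_mean"]),
            np.array(manifest["feature_std"]),
            names,
            manifest["seed"],
            np.array(manifest["train_idx"], dtype=int),
            np.array(manifest["test_idx"], dtype=int),
        )


def fit_qc(
    records: list[tuple[ShapeRecord, str]],
    seed: int = 0,
    members: tuple[str, ...] = DEFAULT_MEMBERS,
    include_neural: bool = False,
    train_fraction: float = 0.8,
) -> QCModelBundle:
    """Fit the voting ensemble on labeled shape records.

    The records are split 80/20 train/test with a seeded shuffle; every
    member is fitted on the standardized training features.  The test
    indices are kept in the bundle so held-out evaluation never touches
    training rows.
    """
    if len(records) < 10:
        raise ValueError("QC fitting needs at least 10 records")
    labels = np.array([1 if lab == FAIL else 0 for _, lab in records])
    if labels.min() == labels.max():
        raise ValueError("QC fitting needs both pass and fail examples")
    names = tuple(members) + (NEURAL_MEMBERS if include_neural else ())
    recs = [r for r, _ in records]
    x_all = records_to_features(recs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(train_fraction * len(records)))
    train_idx, test_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    # guard against single-class training splits
    if labels[train_idx].min() == labels[train_idx].max():
        raise ValueError("seeded split left a single-class training set")
    mean = x_all[train_idx].mean(axis=0)
    std = x_all[train_idx].std(axis=0)
    std[std == 0] = 1.0
    x_train = (x_all[train_idx] - mean) / std
    fitted = {}
    for name in names:
        model = _make_member(name, seed)
        model.fit(x_train, labels[train_idx])
        fitted[name] = model
    return QCModelBundle(fitted, mean, std, names, seed, train_idx, test_idx)


def predict_qc(
    bundle: QCModelBundle, record: ShapeRecord | list[ShapeRecord]
) -> tuple[str, dict] | list[tuple[str, dict]]:
    """Majority-vote label(s) with the per-member votes for audit.

    Ties (even member subsets only) break toward fail.  Returns
    ``(label, votes)`` for a single record or a list thereof.
    """
    single = isinstance(record, ShapeRecord)
    records = [record] if single else record
    votes = bundle.vote_matrix(records)
    n_members = votes.shape[1]
    out = []
    for row in votes:
        n_fail = int(row.sum())
        label = FAIL if 2 * n_fail >= n_members else PASS
        out.append((label, dict(zip(bundle.member_names, (int(v) for v in row)))))
    return out[0] if single else out


@dataclass
class QCEvaluation:
    """Classification quality of QC predictions (positive class = fail)."""

    precision: float
    recall: float
    f1: float
    auc: float | None
    confusion: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.precision, self.recall, self.f1):
            if not 0.0 <= v <= 1.0:
                raise ValueError("classification metrics must be in [0, 1]")


def evaluate_qc(
    predictions: list[str],
    truth: list[str],
    scores: np.ndarray | None = None,
) -> QCEvaluation:
    """Precision/recall/F1 on hard labels, AUC on fail scores.

    AUC uses the mean-vote score ranking with midrank tie handling; when
    the truth contains a single class, AUC is undefined and returned as
    None while the label metrics are still computed.
    """
    if len(predictions) != len(truth) or len(truth) == 0:
        raise ValueError("predictions and truth must be same nonzero length")
    y_true = np.array([1 if t == FAIL else 0 for t in truth])
    y_pred = np.array([1 if p == FAIL else 0 for p in predictions])
    prec = precision_score(y_true, y_pred, zero_division=0)
    rec = recall_score(y_true, y_pred, zero_division=0)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    auc = None
    if y_true.min() != y_true.max():
        auc = float(roc_auc_score(y_true, scores if scores is not None else y_pred))
    return QCEvaluation(
        float(prec), float(rec), float(f1), auc,
        confusion_matrix(y_true, y_pred, labels=[0, 1]),
    )
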