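"""Multi-classifier majority-vote diagnostic.

The diagnostic core: expression values (relative PCR quantities or array
intensities) are log-transformed and mapped per gene to the range 1–100
with parameters frozen on the training set; features are the genes
up-regulated in tumors at an uncorrected t-test p < α on the training
samples; four learners — a linear support vector machine, linear
discriminant analysis, k-nearest neighbours and Gaussian naive Bayes — are
trained on the selected features; and a sample's consensus call is
"tumor" when fewer than 2 of the 4 votes say "control" (equivalently,
3 or more tumor votes). Stratified 10-fold cross-validation with feature
selection refit inside every fold (no leakage) reports per-learner and
consensus accuracy.

The log base only rescales values before min–max mapping, so it does not
affect the result; base 2 is used.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import CONTROL, TUMOR, ExpressionDataset
from .pcr import NormalizedExpression

LEARNERS = ("svm", "lda", "knn", "bayes")


@dataclass
class PreprocessedMatrix:
    """Genes × samples matrix mapped to [1, 100], with frozen mapping."""

    values: pd.DataFrame
    log_min: pd.Series      # per-gene train-set min of log2 values
    log_max: pd.Series      # per-gene train-set max
    constant_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def _as_matrix(raw) -> pd.DataFrame:
    if isinstance(raw, NormalizedExpression):
        return raw.matrix("rq")
    if isinstance(raw, ExpressionDataset):
        return raw.values
    return pd.DataFrame(raw)


def preprocess(raw, train_params: PreprocessedMatrix | None = None) -> PreprocessedMatrix:
    """Log-transform and map each gene to the range 1–100.

    v' = 1 + 99 · (log2 v − min_g) / (max_g − min_g), with min/max taken
    over the training samples. When ``train_params`` is given, its frozen
    per-gene parameters are applied and out-of-sample values are clipped
    to [1, 100]. A constant training gene maps to 1 everywhere and is
    flagged.
    """
    matrix = _as_matrix(raw)
    if (matrix.to_numpy() <= 0).any():
        raise ValueError("log transform needs strictly positive values")
    logged = np.log2(matrix)
    if train_params is None:
        lo = logged.min(axis=1)
        hi = logged.max(axis=1)
        constant = list(lo.index[hi == lo])
    else:
        lo = train_params.log_min.reindex(logged.index)
        hi = train_params.log_max.reindex(logged.index)
        if lo.isna().any():
            missing = list(lo.index[lo.isna()])
            raise ValueError(f"genes absent from training parameters: {missing[:5]}")
        constant = train_params.constant_genes
    span = (hi - lo).replace(0.0, np.nan)
    scaled = 1.0 + 99.0 * logged.sub(lo, axis=0).div(span, axis=0)
    scaled = scaled.fillna(1.0).clip(lower=1.0, upper=100.0)
    return PreprocessedMatrix(scaled, lo, hi, constant)


def select_features(train: PreprocessedMatrix, labels: pd.Series,
                    alpha: float = 0.05, equal_var: bool = False) -> list[str]:
    """Genes up-regulated in tumors at uncorrected t-test p < α.

    Returned sorted by ascending p-value. Raises when nothing passes —
    relax α rather than training on an empty feature set.
    """
    labels = labels.reindex(train.samples)
    tumor = train.values.loc[:, labels == TUMOR].to_numpy()
    control = train.values.loc[:, labels == CONTROL].to_numpy()
    if tumor.shape[1] == 0 or control.shape[1] == 0:
        raise ValueError("both classes must be present for feature selection")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(tumor, control, axis=1, equal_var=equal_var)
    p = np.nan_to_num(p, nan=1.0)
    up = tumor.mean(axis=1) > control.mean(axis=1)
    mask = (p < alpha) & up
    if not mask.any():
        raise ValueError(f"no up-regulated features at alpha={alpha}; relax alpha")
    order = np.argsort(p[mask], kind="stable")
    return list(np.asarray(train.genes)[mask][order])


def _make_learners(knn_k: int, svm_c: float) -> dict:
    return {
        "svm": SVC(kernel="linear", C=svm_c),
        "lda": LinearDiscriminantAnalysis(),
        "knn": KNeighborsClassifier(n_neighbors=knn_k),
        "bayes": GaussianNB(),
    }


def consensus_call(votes: pd.DataFrame) -> pd.Series:
    """Majority-vote consensus: fewer than 2 control votes means tumor.

    A 2–2 split therefore resolves to control — the operating point of the
    rule, read strictly.
    """
    control_votes = (votes == CONTROL).sum(axis=1)
    return pd.Series(np.where(control_votes < 2, TUMOR, CONTROL),
                     index=votes.index)


def _best_up_feature(train: PreprocessedMatrix, labels: pd.Series,
                     equal_var: bool = False) -> list[str]:
    """Single most significant up-regulated gene (fallback when α admits none)."""
    labels = labels.reindex(train.samples)
    tumor = train.values.loc[:, labels == TUMOR].to_numpy()
    control = train.values.loc[:, labels == CONTROL].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(tumor, control, axis=1, equal_var=equal_var)
    p = np.where(tumor.mean(axis=1) > control.mean(axis=1),
                 np.nan_to_num(p, nan=1.0), np.inf)
    return [str(train.genes[int(np.argmin(p))])]


@dataclass
class EnsembleModel:
    """Four trained learners plus frozen preprocessing and feature list."""

    learners: dict
    features: list[str]
    preprocessing: PreprocessedMatrix
    seed: int
    folds: int
    knn_k: int
    alpha: float

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "model": self}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != 1:
            raise ValueError("unknown model archive version")
        return payload["model"]


@dataclass
class EnsemblePrediction:
    """Per-sample votes of the four learners and the consensus call."""

    votes: pd.DataFrame          # samples × learners, values control/tumor
    consensus: pd.Series         # consensus call per sample

    @property
    def control_votes(self) -> pd.Series:
        return (self.votes == CONTROL).sum(axis=1)

    @property
    def score(self) -> pd.Series:
        """Number of tumor votes (0–4).

        A score > 2 (at least 3 tumor votes) coincides exactly with the
        consensus rule "< 2 control votes → tumor".
        """
        return 4 - self.control_votes


def train_ensemble(
    train: PreprocessedMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    seed: int = 0,
    knn_k: int = 5,
    svm_c: float = 1.0,
    folds: int = 10,
) -> tuple[EnsembleModel, pd.DataFrame]:
    """Train the four-learner ensemble with stratified k-fold CV.

    Feature selection is refit on each fold's training part so the
    cross-validated accuracies are leakage-free. The returned model is
    refit on all training data; the cv_report gives mean, min and max
    held-out accuracy per learner and for the majority vote.
    """
    labels = labels.reindex(train.samples)
    counts = labels.value_counts()
    if (counts < folds).any():
        raise ValueError(
            f"stratified {folds}-fold CV needs at least {folds} samples per class")
    x = train.values.T  # samples × genes
    y = labels.to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = {name: [] for name in (*LEARNERS, "consensus")}
    for train_idx, test_idx in skf.split(x, y):
        fold_view = PreprocessedMatrix(
            train.values.iloc[:, train_idx], train.log_min, train.log_max,
            train.constant_genes)
        try:
            feats = select_features(fold_view, labels.iloc[train_idx], alpha=alpha)
        except ValueError:
            # a fold with no feature passing alpha (e.g. null data) still
            # needs a prediction; fall back to the single best candidate
            feats = _best_up_feature(fold_view, labels.iloc[train_idx])
        xtr, xte = x.iloc[train_idx][feats], x.iloc[test_idx][feats]
        ytr, yte = y[train_idx], y[test_idx]
        votes = {}
        for name, learner in _make_learners(knn_k, svm_c).items():
            learner.fit(xtr, ytr)
            pred = learner.predict(xte)
            votes[name] = pred
            fold_acc[name].append(float(np.mean(pred == yte)))
        vote_df = pd.DataFrame(votes, index=xte.index)
        consensus = consensus_call(vote_df)
        fold_acc["consensus"].append(float(np.mean(consensus.to_numpy() == yte)))
    cv_report = pd.DataFrame({
        "mean_accuracy": {k: float(np.mean(v)) for k, v in fold_acc.items()},
        "min_accuracy": {k: float(np.min(v)) for k, v in fold_acc.items()},
        "max_accuracy": {k: float(np.max(v)) for k, v in fold_acc.items()},
    })
    try:
        features = select_features(train, labels, alpha=alpha)
    except ValueError:
        features = _best_up_feature(train, labels)
    learners = _make_learners(knn_k, svm_c)
    for learner in learners.values():
        learner.fit(x[features], y)
    model = EnsembleModel(learners, features, train, seed, folds, knn_k, alpha)
    return model, cv_report


def predict(model: EnsembleModel, samples: PreprocessedMatrix) -> EnsemblePrediction:
    """Vote every sample with the four learners and apply the consensus rule."""
    missing = [f for f in model.features if f not in samples.genes]
    if missing:
        raise ValueError(f"features missing from sample matrix: {missing[:5]}")
    x = samples.values.T[model.features]
    votes = pd.DataFrame(
        {name: learner.predict(x) for name, learner in model.learners.items()},
        index=x.index)
    return EnsemblePrediction(votes, consensus_call(votes))
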