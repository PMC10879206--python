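"""Per-platform ensemble classification by repeated cross-validation.

Each platform gets its own ensemble: in every one of ``r`` repeats the
cohort is split into ``k`` stratified folds, and for every fold a model is
trained on the remaining folds (t-test feature selection with the feature
count tuned by an inner 2-fold cross-validation, then a diagonal linear
discriminant).  A patient therefore accumulates ``r`` out-of-sample class
votes.  The agreement among the votes yields a per-patient confidence
score ``2 * |p - 0.5|`` where ``p`` is the majority fraction: 1 means the
ensemble is unanimous, 0 means a perfect 50-50 split.

For application to an independent cohort, all ``r * k`` fold-trained
models are frozen and applied unchanged, giving each external patient
``r * k`` votes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import PlatformAssay, RunConfig

__all__ = [
    "DLDAModel",
    "EnsemblePredictions",
    "TrainedPlatformEnsemble",
    "select_features_ttest",
    "tune_feature_count",
    "fit_dlda",
    "predict_dlda",
    "run_repeated_cv",
    "compute_confidence",
    "patient_accuracy",
    "train_full_ensemble",
    "apply_ensemble",
]

# Relative floor applied to pooled per-feature variances so the Gaussian
# densities stay finite on (near-)constant features.
_VARIANCE_FLOOR_FACTOR = 1e-8


def _platform_rng(seed: int, platform: str, stream: int) -> np.random.Generator:
    """Seeded generator that depends only on (seed, platform, stream).

    Using a per-platform stream makes each platform's ensemble
    reproducible regardless of the order in which platforms are run, and
    keeps the vote tie-break stream (stream=1) independent of the fold
    randomness (stream=0).
    """
    return np.random.default_rng([seed, zlib.crc32(platform.encode()), stream])


# ---------------------------------------------------------------------------
# Feature selection


def select_features_ttest(
    matrix: pd.DataFrame, labels: pd.Series | np.ndarray, count: int
) -> list[str]:
    """Pick the ``count`` features with largest absolute Welch t statistic.

    The two-sample t statistic with unequal variances is computed per
    feature between the two classes; features are ranked by ``|t|`` and
    ties resolve by column order.  ``count`` is clipped to the number of
    features.  The selected identifiers are returned in column order.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    X = matrix.to_numpy(dtype=float)
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs >= 2 samples for the t statistic")
    se2 = a.var(axis=0, ddof=1) / len(a) + b.var(axis=0, ddof=1) / len(b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(diff) / np.sqrt(se2)
    # 0/0 (constant, equal means) carries no signal; x/0 separates perfectly.
    t = np.where(np.isnan(t), 0.0, t)
    t = np.where(np.isinf(t), np.finfo(float).max, t)
    count = min(count, X.shape[1])
    order = np.argsort(-t, kind="stable")[:count]
    keep = np.zeros(X.shape[1], dtype=bool)
    keep[order] = True
    return [f for f, k in zip(matrix.columns, keep) if k]


def tune_feature_count(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    candidate_counts: tuple[int, ...] | list[int],
    rng: np.random.Generator | None = None,
) -> int:
    """Choose a feature count by inner 2-fold cross-validated balanced accuracy.

    Candidates are clipped to the number of features (then de-duplicated);
    ties break toward the smaller count for parsimony.
    """
    if not candidate_counts:
        raise ValueError("candidate_counts must be non-empty")
    n_features = matrix.shape[1]
    candidates = sorted({min(int(c), n_features) for c in candidate_counts})
    if len(candidates) == 1:
        return candidates[0]
    rng = rng or np.random.default_rng(0)
    y = np.asarray(labels)
    skf = StratifiedKFold(
        n_splits=2, shuffle=True, random_state=int(rng.integers(2**31))
    )
    scores = np.zeros(len(candidates))
    for train_idx, test_idx in skf.split(matrix, y):
        Xtr, ytr = matrix.iloc[train_idx], y[train_idx]
        Xte, yte = matrix.iloc[test_idx], y[test_idx]
        for i, count in enumerate(candidates):
            feats = select_features_ttest(Xtr, ytr, count)
            model = fit_dlda(Xtr[feats], ytr)
            pred = predict_dlda(model, Xte)
            scores[i] += _balanced_accuracy(yte, pred)
    return candidates[int(np.argmax(scores))]  # argmax -> first max -> smallest


def _balanced_accuracy(truth: np.ndarray, pred: np.ndarray) -> float:
    classes = np.unique(truth)
    return float(np.mean([np.mean(pred[truth == c] == c) for c in classes]))


# ---------------------------------------------------------------------------
# Diagonal linear discriminant analysis


@dataclass(frozen=True)
class DLDAModel:
    """Gaussian classifier with class means and a shared diagonal covariance.

    ``variances`` holds the pooled within-class per-feature variances,
    floored at a small positive value; ``priors`` are the empirical class
    frequencies and sum to one.
    """

    classes: tuple
    features: tuple
    means: np.ndarray  # (n_classes, n_features)
    variances: np.ndarray  # (n_features,)
    priors: np.ndarray  # (n_classes,)


def fit_dlda(
    matrix: pd.DataFrame, labels: pd.Series | np.ndarray, classes: tuple | None = None
) -> DLDAModel:
    """Fit a diagonal LDA: per-class means, pooled per-feature variances.

    ``classes`` fixes the class order (the first-listed class wins exact
    discriminant ties); by default classes are taken in sorted order.
    """
    y = np.asarray(labels)
    found = np.unique(y)
    if classes is None:
        classes = tuple(found)
    elif set(found) - set(classes):
        raise ValueError(f"labels contain classes outside {classes}")
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    counts = np.array([(y == c).sum() for c in classes])
    if (counts == 0).any():
        raise ValueError("every class needs at least one sample")
    # pooled within-class sum of squares / (n - n_classes); falls back to
    # overall variance if only one sample per class.
    ss = np.zeros(p)
    for c, mu in zip(classes, means):
        ss += ((X[y == c] - mu) ** 2).sum(axis=0)
    dof = max(n - len(classes), 1)
    variances = ss / dof
    if (variances > 0).any():
        floor = _VARIANCE_FLOOR_FACTOR * variances[variances > 0].mean()
    else:
        # classes are internally constant; fall back to the overall spread
        overall = X.var(axis=0, ddof=0)
        if not (overall > 0).any():
            raise ValueError("zero pooled variance for every feature")
        floor = _VARIANCE_FLOOR_FACTOR * overall[overall > 0].mean()
    variances = np.maximum(variances, floor)
    priors = counts / counts.sum()
    return DLDAModel(
        classes=tuple(classes),
        features=tuple(matrix.columns),
        means=means,
        variances=variances,
        priors=priors,
    )


def predict_dlda(model: DLDAModel, matrix: pd.DataFrame) -> np.ndarray:
    """Classify each row by the largest Gaussian discriminant.

    The discriminant of class ``c`` is ``log prior_c - 0.5 * sum_j
    (x_j - mu_cj)^2 / sigma_j^2`` (shared-variance terms cancel).  Exact
    ties go to the first-listed class.
    """
    missing = [f for f in model.features if f not in matrix.columns]
    if missing:
        raise KeyError(f"matrix lacks model feature(s): {missing}")
    X = matrix[list(model.features)].to_numpy(dtype=float)
    scores = np.empty((X.shape[0], len(model.classes)))
    for i, mu in enumerate(model.means):
        scores[:, i] = np.log(model.priors[i]) - 0.5 * (
            (X - mu) ** 2 / model.variances
        ).sum(axis=1)
    idx = np.argmax(scores, axis=1)  # first max -> first-listed class on ties
    return np.asarray(model.classes, dtype=object)[idx]


# ---------------------------------------------------------------------------
# Votes, confidence and accuracy


def compute_confidence(votes, rng: np.random.Generator | None = None):
    """Majority class and confidence ``2|p - 0.5|`` of a vote list.

    ``p`` is the fraction of votes cast for the majority class, so the
    confidence is 1 when the ensemble is unanimous and 0 on a perfect
    50-50 split, in which case the returned class is drawn uniformly from
    ``rng``.
    """
    votes = list(votes)
    if not votes:
        raise ValueError("votes must be non-empty")
    values, counts = np.unique(np.asarray(votes, dtype=object), return_counts=True)
    top = counts.max()
    winners = values[counts == top]
    if len(winners) > 1:
        rng = rng or np.random.default_rng(0)
        majority = winners[rng.integers(len(winners))]
    else:
        majority = winners[0]
    p = top / len(votes)
    return majority, 2.0 * abs(p - 0.5)


def patient_accuracy(votes, true_class) -> float:
    """Fraction of ensemble votes that equal the true class."""
    votes = list(votes)
    if not votes:
        raise ValueError("votes must be non-empty")
    return float(np.mean([v == true_class for v in votes]))


@dataclass
class EnsemblePredictions:
    """Per-patient ensemble votes for one platform with derived summaries.

    ``votes`` is a ``patients x n_votes`` table of class labels (``r``
    columns in single-cohort mode, ``r * k`` when a frozen ensemble is
    applied externally).  ``majority``, ``agreement`` (the majority
    fraction ``p``) and ``confidence`` are per-patient series computed at
    construction; 50-50 ties are resolved from a dedicated seeded stream.
    """

    platform: str
    votes: pd.DataFrame
    classes: tuple
    majority: pd.Series = field(init=False)
    agreement: pd.Series = field(init=False)
    confidence: pd.Series = field(init=False)
    tie_seed: int = 0

    def __post_init__(self) -> None:
        rng = np.random.default_rng([self.tie_seed, zlib.crc32(self.platform.encode()), 1])
        majority, agreement = [], []
        for _, row in self.votes.iterrows():
            cls, conf = compute_confidence(row.tolist(), rng)
            majority.append(cls)
            agreement.append((conf / 2.0) + 0.5)
        self.majority = pd.Series(majority, index=self.votes.index, name="majority")
        self.agreement = pd.Series(agreement, index=self.votes.index, name="agreement")
        self.confidence = pd.Series(
            2.0 * np.abs(self.agreement - 0.5), index=self.votes.index, name="confidence"
        )

    @property
    def n_votes(self) -> int:
        return self.votes.shape[1]

    def accuracy(self, truth: pd.Series) -> pd.Series:
        """Per-patient vote-level accuracy against the true classes."""
        acc = {
            pid: patient_accuracy(self.votes.loc[pid].tolist(), truth[pid])
            for pid in self.votes.index
        }
        return pd.Series(acc, name="accuracy")

    def to_table(self, truth: pd.Series | None = None) -> pd.DataFrame:
        """Summary table: votes for positive class, majority, confidence."""
        positive = self.classes[-1]
        table = pd.DataFrame(
            {
                "platform": self.platform,
                "votes_positive": (self.votes == positive).sum(axis=1),
                "votes_total": self.n_votes,
                "majority": self.majority,
                "confidence": self.confidence,
            }
        )
        if truth is not None:
            table["accuracy"] = self.accuracy(truth)
        return table


# ---------------------------------------------------------------------------
# Repeated cross-validation


def _fit_fold(Xtr, ytr, config, classes, rng):
    count = tune_feature_count(Xtr, ytr, config.feature_counts, rng)
    feats = select_features_ttest(Xtr, ytr, count)
    return fit_dlda(Xtr[feats], ytr, classes=classes)


def run_repeated_cv(
    assay: PlatformAssay, labels: pd.Series, config: RunConfig
) -> EnsemblePredictions:
    """r-repeat stratified k-fold cross-validation on one platform.

    Every repeat contributes one out-of-sample vote per patient, so each
    patient ends with exactly ``config.repeats`` votes.  Folds are
    stratified by class so both classes appear in every training fold.
    Fully reproducible from ``config.seed``.
    """
    labels = labels.loc[assay.samples]
    y = labels.to_numpy()
    classes = tuple(sorted(np.unique(y)))
    min_class = min((y == c).sum() for c in classes)
    if min_class < config.folds:
        raise ValueError(
            f"smallest class has {min_class} samples; cannot stratify into "
            f"{config.folds} folds"
        )
    rng = _platform_rng(config.seed, assay.name, 0)
    votes = pd.DataFrame(
        index=assay.samples, columns=[f"rep{r}" for r in range(config.repeats)], dtype=object
    )
    for rep in range(config.repeats):
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for train_idx, test_idx in skf.split(assay.matrix, y):
            model = _fit_fold(assay.matrix.iloc[train_idx], y[train_idx], config, classes, rng)
            pred = predict_dlda(model, assay.matrix.iloc[test_idx])
            votes.iloc[test_idx, rep] = pred
    return EnsemblePredictions(
        platform=assay.name, votes=votes, classes=classes, tie_seed=config.seed
    )


@dataclass
class TrainedPlatformEnsemble:
    """The ``r * k`` fold-trained models of one platform, frozen for reuse."""

    platform: str
    models: list[DLDAModel]
    classes: tuple
    training_features: tuple
    seed: int

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def required_features(self) -> list[str]:
        needed: set = set()
        for m in self.models:
            needed.update(m.features)
        return sorted(needed)


def train_full_ensemble(
    assay: PlatformAssay, labels: pd.Series, config: RunConfig
) -> TrainedPlatformEnsemble:
    """Train and keep all ``r * k`` fold models of the repeated CV.

    The fold models themselves form the ensemble for external
    application; nothing is refit on the full cohort.  The fold stream is
    shared with :func:`run_repeated_cv`, so under the same seed the
    stored models reproduce the same held-out votes.
    """
    labels = labels.loc[assay.samples]
    y = labels.to_numpy()
    classes = tuple(sorted(np.unique(y)))
    min_class = min((y == c).sum() for c in classes)
    if min_class < config.folds:
        raise ValueError(
            f"smallest class has {min_class} samples; cannot stratify into "
            f"{config.folds} folds"
        )
    rng = _platform_rng(config.seed, assay.name, 0)
    models: list[DLDAModel] = []
    for _ in range(config.repeats):
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for train_idx, _test_idx in skf.split(assay.matrix, y):
            models.append(
                _fit_fold(assay.matrix.iloc[train_idx], y[train_idx], config, classes, rng)
            )
    return TrainedPlatformEnsemble(
        platform=assay.name,
        models=models,
        classes=classes,
        training_features=tuple(assay.features),
        seed=config.seed,
    )


def apply_ensemble(
    ensemble: TrainedPlatformEnsemble, external_assay: PlatformAssay
) -> EnsemblePredictions:
    """Apply a frozen ensemble: each external patient gets ``r * k`` votes."""
    missing = sorted(set(ensemble.required_features) - set(external_assay.features))
    if missing:
        raise KeyError(
            f"external assay {external_assay.name!r} lacks feature(s) required by "
            f"the trained ensemble: {missing}"
        )
    votes = pd.DataFrame(
        index=external_assay.samples,
        columns=[f"model{i}" for i in range(ensemble.n_models)],
        dtype=object,
    )
    for i, model in enumerate(ensemble.models):
        votes.iloc[:, i] = predict_dlda(model, external_assay.matrix)
    return EnsemblePredictions(
        platform=ensemble.platform, votes=votes, classes=ensemble.classes,
        tie_seed=ensemble.seed,
    )
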