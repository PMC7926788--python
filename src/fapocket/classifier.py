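"""MLP pocket classifier: training, 5-fold CV, scoring, two-model consensus.

A multilayer perceptron maps the 14-descriptor pocket vector to a score in
[0, 1] (0 = negative match, 1 = positive match).  A pocket is called
positive only when its score is *strictly* greater than the cutoff (default
0.5); the consensus call requires positivity under both models (the
all-species and the human-trained one), which makes the consensus
false-positive rate at most the smaller per-model rate by construction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .detect import Pocket
from .features import SCHEMA_VERSION, FeatureNormalizer

__all__ = [
    "ClassifierParams", "TrainedModel", "PocketScore", "CVReport",
    "train", "predict", "cross_validate", "consensus",
    "save_model", "load_model",
]


@dataclass(frozen=True)
class ClassifierParams:
    hidden_layers: tuple[int, ...] = (32,)
    activation: str = "logistic"
    max_epochs: int = 500
    early_stop_patience: int = 20
    l2: float = 1e-4
    learning_rate: float = 1e-2
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))


@dataclass
class TrainedModel:
    params: ClassifierParams
    feature_schema_version: str
    normalizer: FeatureNormalizer
    mlp: MLPClassifier
    provenance_digest: str
    converged: bool

    def weights_digest(self) -> str:
        h = hashlib.sha256()
        for w in self.mlp.coefs_ + self.mlp.intercepts_:
            h.update(np.ascontiguousarray(w).tobytes())
        return h.hexdigest()


@dataclass
class PocketScore:
    pocket: Pocket | int | None
    score: float
    positive: bool


@dataclass
class CVReport:
    k: int
    fold_accuracies: list[float]
    mean_accuracy: float
    pooled_accuracy: float
    seed: int
    fold_sizes: list[int] = field(default_factory=list)
    fold_positives: list[int] = field(default_factory=list)


class SchemaMismatchError(ValueError):
    """Feature schema of the input does not match the trained model's."""


def _validate_xy(X: np.ndarray, y: np.ndarray) -> None:
    X = np.asarray(X, dtype=float)
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"non-finite feature at row {r}, column {c}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"need both classes in y, got {classes.tolist()}")
    if X.shape[0] < 10:
        raise ValueError(f"need >= 10 rows to train, got {X.shape[0]}")


def train(
    X: np.ndarray,
    y: np.ndarray,
    params: ClassifierParams = ClassifierParams(),
    schema_version: str = SCHEMA_VERSION,
) -> TrainedModel:
    """Fit normalization + MLP.  Deterministic given the seed.

    Normalization statistics are computed from the training rows only and
    stored in the model.  Training stops when the loss has not improved by
    more than 1e-6 for `early_stop_patience` epochs (a loss-plateau rule:
    pocket training sets are small enough that accuracy on a 10% validation
    split is too coarse a stopping signal), or at `max_epochs`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _validate_xy(X, y)
    normalizer = FeatureNormalizer().fit(X)
    Xn = normalizer.transform(X)
    mlp = MLPClassifier(
        hidden_layer_sizes=params.hidden_layers,
        activation=params.activation,
        alpha=params.l2,
        learning_rate_init=params.learning_rate,
        max_iter=params.max_epochs,
        early_stopping=False,
        tol=1e-6,
        n_iter_no_change=params.early_stop_patience,
        random_state=params.seed,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(Xn, y)
    digest = hashlib.sha256(X.tobytes() + y.tobytes()).hexdigest()
    return TrainedModel(
        params=params,
        feature_schema_version=schema_version,
        normalizer=normalizer,
        mlp=mlp,
        provenance_digest=digest,
        converged=mlp.n_iter_ < params.max_epochs,
    )


def predict(
    model: TrainedModel,
    X: np.ndarray,
    schema_version: str = SCHEMA_VERSION,
    pockets: list | None = None,
) -> list[PocketScore]:
    """Score rows of X; positive iff score strictly exceeds the threshold."""
    if schema_version != model.feature_schema_version:
        raise SchemaMismatchError(
            f"feature schema {schema_version!r} != model's "
            f"{model.feature_schema_version!r}"
        )
    X = np.asarray(X, dtype=float)
    scores = model.mlp.predict_proba(model.normalizer.transform(X))[:, 1]
    thr = model.params.threshold
    refs = pockets if pockets is not None else list(range(len(scores)))
    return [
        PocketScore(pocket=ref, score=float(s), positive=bool(s > thr))
        for ref, s in zip(refs, scores)
    ]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    params: ClassifierParams = ClassifierParams(),
    k: int = 5,
) -> CVReport:
    """Stratified k-fold CV, refitting from scratch per fold.

    Per-fold accuracy is (TP+TN)/n on the held-out fold only; the report
    carries both the mean of the fold accuracies and the pooled accuracy
    over all held-out predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _validate_xy(X, y)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members, need >= {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=params.seed)
    fold_acc: list[float] = []
    fold_sizes: list[int] = []
    fold_pos: list[int] = []
    n_correct = 0
    for train_idx, test_idx in skf.split(X, y):
        assert len(np.intersect1d(train_idx, test_idx)) == 0
        model = train(X[train_idx], y[train_idx], params)
        scores = predict(model, X[test_idx])
        pred = np.array([s.positive for s in scores], dtype=int)
        correct = int((pred == y[test_idx]).sum())
        fold_acc.append(correct / len(test_idx))
        fold_sizes.append(len(test_idx))
        fold_pos.append(int(y[test_idx].sum()))
        n_correct += correct
    return CVReport(
        k=k,
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        pooled_accuracy=n_correct / len(y),
        seed=params.seed,
        fold_sizes=fold_sizes,
        fold_positives=fold_pos,
    )


def consensus(
    scores_all_species: list[PocketScore], scores_human: list[PocketScore]
) -> list[bool]:
    """Consensus-positive iff positive under BOTH models (aligned lists)."""
    if len(scores_all_species) != len(scores_human):
        raise ValueError(
            f"score lists differ in length: {len(scores_all_species)} vs "
            f"{len(scores_human)}"
        )
    return [a.positive and b.positive
            for a, b in zip(scores_all_species, scores_human)]


def save_model(model: TrainedModel, path) -> None:
    """Persist as a single archive: params, schema, normalization, weights."""
    joblib.dump({
        "params": asdict(model.params),
        "feature_schema_version": model.feature_schema_version,
        "normalizer_mean": model.normalizer.mean_,
        "normalizer_scale": model.normalizer.scale_,
        "mlp": model.mlp,
        "provenance_digest": model.provenance_digest,
        "converged": model.converged,
    }, path)


def load_model(path) -> TrainedModel:
    blob = joblib.load(path)
    normalizer = FeatureNormalizer()
    normalizer.mean_ = blob["normalizer_mean"]
    normalizer.scale_ = blob["normalizer_scale"]
    params = blob["params"]
    params["hidden_layers"] = tuple(params["hidden_layers"])
    return TrainedModel(
        params=ClassifierParams(**params),
        feature_schema_version=blob["feature_schema_version"],
        normalizer=normalizer,
        mlp=blob["mlp"],
        provenance_digest=blob["provenance_digest"],
        converged=blob["converged"],
    )
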