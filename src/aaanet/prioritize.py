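"""Resampled classifier training and candidate-gene calling.

The protocol: curated disease genes are the positive class; an equal-sized
negative class is sampled uniformly from the remaining network genes.  The
seven topology features feed one of four classifiers (SVM-RBF, naive Bayes,
random forest, k-nearest neighbors).  Hyperparameters are chosen by 10-fold
cross-validated grid search on a 70% training split; the whole procedure is
repeated with re-randomized negative samples and splits, and every
non-positive network gene receives one vote per repetition in which the
trained model classifies it as a disease gene.  Candidates are called from
the vote table (default: majority of repetitions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_COLUMNS, FeatureTable, compute_feature_table
from .network import PPINetwork

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = "positive", "negative"

CLASSIFIERS = ("svm", "nb", "rf", "knn")

#: default hyperparameter grids, fully overridable through RunConfig.grids
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"gamma": [0.01, 0.1, 1.0], "cost": [0.1, 1.0, 10.0]},
    "rf": {"mtry": [1, 2, 3], "ntree": [100, 500]},
    "knn": {"k": [1, 3, 5, 7, 9]},
    "nb": {},
}


@dataclass
class LabeledDataset:
    """Feature rows with positive/negative labels.

    Positives and negatives are disjoint and together cover exactly the
    feature rows.
    """

    features: pd.DataFrame  # indexed by gene, columns FEATURE_COLUMNS
    labels: pd.Series  # gene -> POSITIVE / NEGATIVE

    def __post_init__(self):
        if not self.features.index.equals(self.labels.index):
            raise ValueError("labels must cover exactly the feature-table genes")
        bad = set(self.labels.unique()) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"invalid labels: {bad}")

    @property
    def positives(self) -> set[str]:
        return set(self.labels.index[self.labels == POSITIVE])

    @property
    def negatives(self) -> set[str]:
        return set(self.labels.index[self.labels == NEGATIVE])

    @property
    def genes(self) -> list[str]:
        return list(self.features.index)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def X(self) -> np.ndarray:
        return self.features[FEATURE_COLUMNS].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return (self.labels == POSITIVE).to_numpy(dtype=int)


@dataclass
class RunConfig:
    """Resampling-protocol parameters.

    Defaults follow the published protocol: 70/30 stratified split, 10-fold
    CV hyperparameter tuning, 200 repetitions, base seed 123, balanced
    negative sampling re-drawn every repetition, majority-vote candidate
    calling.
    """

    classifier: str = "rf"
    train_fraction: float = 0.7
    n_reps: int = 200
    cv_folds: int = 10
    base_seed: int = 123
    grids: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GRIDS.items()})
    negative_ratio: float = 1.0
    resample_negatives_per_rep: bool = True
    tune_every_rep: bool = False
    candidate_rule: str = "majority"  # any | majority | fraction
    candidate_tau: float | None = None

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvalMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def sample_negatives(
    net: PPINetwork, positives: set[str], ratio: float = 1.0, seed: int = 0
) -> set[str]:
    """Uniform sample (without replacement) of non-positive network genes.

    Size is round(ratio * |positives in network|); deterministic per seed.
    """
    pos_in_net = positives & net.nodes
    pool = sorted(net.nodes - positives)
    k = round(ratio * len(pos_in_net))
    if k > len(pool):
        raise ValueError(
            f"cannot sample {k} negatives from {len(pool)} non-positive nodes"
        )
    rng = np.random.default_rng(seed)
    return set(rng.choice(pool, size=k, replace=False))


def split_train_test(
    ds: LabeledDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified split preserving class proportions within +/-1 gene."""
    counts = ds.labels.value_counts()
    if counts.get(POSITIVE, 0) < 2 or counts.get(NEGATIVE, 0) < 2:
        raise ValueError("both classes need >= 2 members to stratify")
    idx_train, idx_test = train_test_split(
        ds.features.index,
        train_size=train_fraction,
        stratify=ds.labels,
        random_state=seed,
        shuffle=True,
    )
    return (
        LabeledDataset(ds.features.loc[idx_train], ds.labels.loc[idx_train]),
        LabeledDataset(ds.features.loc[idx_test], ds.labels.loc[idx_test]),
    )


def _make_estimator(classifier: str, params: dict, seed: int):
    if classifier == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    SVC(
                        kernel="rbf",
                        gamma=params.get("gamma", "scale"),
                        C=params.get("cost", 1.0),
                    ),
                ),
            ]
        )
    if classifier == "nb":
        return GaussianNB()
    if classifier == "rf":
        return RandomForestClassifier(
            max_features=params.get("mtry", 2),
            n_estimators=params.get("ntree", 500),
            random_state=seed,
        )
    if classifier == "knn":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", KNeighborsClassifier(n_neighbors=params.get("k", 5))),
            ]
        )
    raise ValueError(f"unknown classifier {classifier!r}")


def _sklearn_grid(classifier: str, grid: dict) -> dict:
    """Map protocol parameter names to sklearn estimator parameters."""
    names = {
        "svm": {"gamma": "clf__gamma", "cost": "clf__C"},
        "rf": {"mtry": "max_features", "ntree": "n_estimators"},
        "knn": {"k": "clf__n_neighbors"},
        "nb": {},
    }[classifier]
    return {names[p]: list(v) for p, v in grid.items()}


@dataclass
class TrainedModel:
    """Fitted classifier plus the hyperparameters chosen by CV."""

    classifier: str
    estimator: object
    params: dict
    cv_accuracy: float | None = None

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """0/1 predictions (1 = positive class)."""
        return np.asarray(self.estimator.predict(features[FEATURE_COLUMNS].to_numpy(dtype=float)))

    def score(self, features: pd.DataFrame) -> np.ndarray:
        """Positive-class score (probability, or SVM decision value)."""
        X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            pos_col = list(est.classes_).index(1)
            return proba[:, pos_col]
        return np.asarray(est.decision_function(X))


def tune_and_train(train: LabeledDataset, cfg: RunConfig, seed: int) -> TrainedModel:
    """Grid-search by mean CV accuracy over stratified folds, then refit.

    Ties break toward the first grid point in deterministic iteration order
    (sklearn keeps the first best-ranked candidate).  An empty grid (naive
    Bayes) skips the search and fits default parameters.
    """
    y = train.y
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training set is single-class")
    grid = cfg.grids.get(cfg.classifier, {})
    if not grid:
        est = _make_estimator(cfg.classifier, {}, seed)
        est.fit(train.X, y)
        return TrainedModel(cfg.classifier, est, {})
    if cfg.cv_folds > min(n_pos, n_neg):
        raise ValueError(
            f"cv_folds={cfg.cv_folds} exceeds smaller class size {min(n_pos, n_neg)}"
        )
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_estimator(cfg.classifier, {}, seed),
        _sklearn_grid(cfg.classifier, grid),
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(train.X, y)
    inverse = {
        "svm": {"clf__gamma": "gamma", "clf__C": "cost"},
        "rf": {"max_features": "mtry", "n_estimators": "ntree"},
        "knn": {"clf__n_neighbors": "k"},
    }[cfg.classifier]
    chosen = {inverse[k]: v for k, v in search.best_params_.items()}
    return TrainedModel(
        cfg.classifier, search.best_estimator_, chosen, float(search.best_score_)
    )


def fit_with_params(
    train: LabeledDataset, cfg: RunConfig, params: dict, seed: int
) -> TrainedModel:
    """Fit the configured classifier with fixed hyperparameters (no search)."""
    y = train.y
    if y.sum() in (0, len(y)):
        raise ValueError("training set is single-class")
    est = _make_estimator(cfg.classifier, params, seed)
    est.fit(train.X, y)
    return TrainedModel(cfg.classifier, est, dict(params))


def evaluate(model: TrainedModel, test: LabeledDataset) -> EvalMetrics:
    """Accuracy/precision/recall/F1 with the disease class as positive, plus
    trapezoidal ROC AUC of the positive-class score.

    Zero-division (no predicted positives, or no true positives) yields 0
    with a warning; a single-class test set makes AUC undefined and raises.
    """
    y_true = test.y
    if y_true.sum() in (0, len(y_true)):
        raise ValueError("test set contains a single class; AUC undefined")
    y_pred = model.predict(test.features)
    scores = model.score(test.features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec = precision_score(y_true, y_pred, zero_division=0)
        rec = recall_score(y_true, y_pred, zero_division=0)
        f1 = f1_score(y_true, y_pred, zero_division=0)
    if y_pred.sum() == 0:
        warnings.warn("no genes predicted positive; precision set to 0", stacklevel=2)
    return EvalMetrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        auc=float(roc_auc_score(y_true, scores)),
    )


@dataclass
class RunResult:
    """Per-repetition metrics plus the cumulative vote table."""

    metrics: list[EvalMetrics]
    votes: pd.Series  # gene -> votes over scored genes (non-positive nodes)
    n_reps_scored: int
    chosen_params: list[dict]
    config: RunConfig

    def metrics_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(m) for m in self.metrics])
        df.insert(0, "rep", range(len(df)))
        return df

    def mean_metric(self, name: str) -> float:
        return float(np.mean([getattr(m, name) for m in self.metrics]))


def repeated_runs(
    net: PPINetwork,
    positives: set[str],
    cfg: RunConfig,
    feature_table: FeatureTable | None = None,
) -> RunResult:
    """Run the full resampling protocol.

    Per repetition i (rep seed = base_seed + i): sample negatives, assemble
    the labeled dataset, stratified 70/30 split, CV-tune (first repetition,
    or every repetition when ``tune_every_rep``), fit, evaluate on the test
    split, then classify EVERY non-positive network gene and record a vote
    when it is predicted positive.  Deterministic given base_seed.

    The feature table depends only on the network and the positive set, so
    it is computed once (or supplied precomputed) and rows are looked up.
    """
    pos_in_net = positives & net.nodes
    if not pos_in_net:
        raise ValueError("no positive genes present in the network")
    if pos_in_net != positives:
        logger.warning(
            "%d positive gene(s) absent from the network were dropped",
            len(positives - pos_in_net),
        )
    all_genes = sorted(net.nodes)
    if feature_table is None:
        feature_table = compute_feature_table(net, pos_in_net, all_genes)
    feats = feature_table.data
    scored_genes = sorted(net.nodes - pos_in_net)
    votes = pd.Series(0, index=pd.Index(scored_genes, name="gene"), dtype=int)

    fixed_negatives: set[str] | None = None
    if not cfg.resample_negatives_per_rep:
        fixed_negatives = sample_negatives(
            net, pos_in_net, cfg.negative_ratio, seed=cfg.base_seed
        )

    metrics: list[EvalMetrics] = []
    chosen_params: list[dict] = []
    tuned: dict | None = None
    for rep in range(cfg.n_reps):
        rep_seed = cfg.base_seed + rep
        try:
            negatives = (
                fixed_negatives
                if fixed_negatives is not None
                else sample_negatives(net, pos_in_net, cfg.negative_ratio, seed=rep_seed)
            )
            genes = sorted(pos_in_net) + sorted(negatives)
            labels = pd.Series(
                [POSITIVE] * len(pos_in_net) + [NEGATIVE] * len(negatives),
                index=pd.Index(genes, name="gene"),
            )
            ds = LabeledDataset(feats.loc[genes], labels)
            train, test = split_train_test(ds, cfg.train_fraction, seed=rep_seed)
            if cfg.tune_every_rep or tuned is None:
                model = tune_and_train(train, cfg, seed=rep_seed)
                tuned = model.params
            else:
                model = fit_with_params(train, cfg, tuned, seed=rep_seed)
            metrics.append(evaluate(model, test))
            chosen_params.append(dict(model.params))
            preds = model.predict(feats.loc[scored_genes])
            votes += pd.Series(preds, index=votes.index, dtype=int)
        except Exception as exc:
            raise RuntimeError(f"repetition {rep} failed: {exc}") from exc
    return RunResult(
        metrics=metrics,
        votes=votes,
        n_reps_scored=cfg.n_reps,
        chosen_params=chosen_params,
        config=cfg,
    )


def compare_classifiers(
    net: PPINetwork,
    positives: set[str],
    cfg: RunConfig,
    classifiers: tuple[str, ...] = CLASSIFIERS,
    feature_table: FeatureTable | None = None,
) -> dict[str, RunResult]:
    """Run several classifiers under identical rep-seeds.

    Each classifier sees the same base_seed, hence the same per-repetition
    negative samples and train/test splits, so per-rep metric differences
    between classifiers are paired.
    """
    from dataclasses import replace

    pos_in_net = positives & net.nodes
    if feature_table is None:
        feature_table = compute_feature_table(net, pos_in_net, sorted(net.nodes))
    return {
        name: repeated_runs(
            net, positives, replace(cfg, classifier=name), feature_table=feature_table
        )
        for name in classifiers
    }


def call_candidates(
    votes: pd.Series,
    n_reps_scored: int,
    rule: str = "majority",
    tau: float | None = None,
) -> pd.DataFrame:
    """Call candidate genes from the vote table.

    Rules: "any" (>= 1 vote), "majority" (> n_reps/2), "fraction"
    (vote_fraction >= tau, tau in (0, 1]).  Output sorted by vote_fraction
    descending, ties by gene symbol.
    """
    if votes.empty:
        raise ValueError("empty vote table")
    if rule == "fraction":
        if tau is None or not 0 < tau <= 1:
            raise ValueError("rule 'fraction' needs tau in (0, 1]")
    elif rule not in ("any", "majority"):
        raise ValueError(f"unknown candidate rule {rule!r}")
    frac = votes / n_reps_scored
    if rule == "any":
        called = votes >= 1
    elif rule == "majority":
        called = votes > n_reps_scored / 2
    else:
        called = frac >= tau
    out = pd.DataFrame(
        {
            "gene": votes.index,
            "votes": votes.to_numpy(),
            "n_reps_scored": n_reps_scored,
            "vote_fraction": frac.to_numpy(),
            "called": called.to_numpy(),
        }
    )
    out = out.sort_values(
        ["vote_fraction", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
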