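"""Integrative missense pathogenicity score (HM score).

Assembles a 13-feature matrix (macaque + human allele frequencies and
eleven in-silico scores) for missense variants with matched dual-genome
amino-acid consequences, benchmarks seven classifier families by
stratified k-fold cross-validated AUC, refits the winning family on all
labelled data, scores unlabelled cohort variants with a calibrated
probability in [0, 1], and applies top-percentile thresholding.

The modelling surface follows the model/results idiom: build an
:class:`HMScoreModel` from a labelled matrix, call :meth:`fit`, and
read the leaderboard, the cross-validated AUCs and the fitted scorer
off the returned :class:`HMScoreResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

#: the 13 features, in schema order: two allele frequencies plus eleven
#: in-silico scores
FEATURE_COLUMNS = [
    "macaque_af",
    "human_af",
    "cadd_phred",
    "revel",
    "polyphen2_hvar",
    "mutation_assessor",
    "metasvm",
    "metalr",
    "phylop100",
    "phastcons100",
    "vest3",
    "dann",
    "gerp",
]

LABELS = ("pathogenic", "benign")

ENSEMBLE_FAMILY = "ensemble"


def _scaled(clf) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", clf),
        ]
    )


def _unscaled(clf) -> Pipeline:
    return Pipeline([("impute", SimpleImputer(strategy="median")), ("clf", clf)])


def _default_families() -> dict[str, Callable[[int], Pipeline]]:
    """Registered classifier families, in fixed (tie-breaking) order.

    Hyperparameters are deliberately small-scale so that a full
    leaderboard run is deterministic given the seed and completes on a
    single CPU in minutes.
    """
    return {
        "random_forest": lambda seed: _unscaled(
            RandomForestClassifier(n_estimators=150, random_state=seed, n_jobs=1)
        ),
        "naive_bayes": lambda seed: _unscaled(GaussianNB()),
        "logistic_regression": lambda seed: _scaled(
            LogisticRegression(max_iter=2000, random_state=seed)
        ),
        "tree_bagging": lambda seed: _unscaled(
            BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=seed),
                n_estimators=60,
                random_state=seed,
                n_jobs=1,
            )
        ),
        "svm": lambda seed: _scaled(
            CalibratedClassifierCV(
                SVC(C=1.0, kernel="rbf", random_state=seed, cache_size=500),
                method="sigmoid",
                cv=3,
                ensemble=False,
            )
        ),
        "neural_network": lambda seed: _scaled(
            MLPClassifier(
                hidden_layer_sizes=(16,),
                max_iter=500,
                tol=1e-3,
                random_state=seed,
            )
        ),
    }


DEFAULT_FAMILY_ORDER = [
    "random_forest",
    "naive_bayes",
    "logistic_regression",
    "tree_bagging",
    "svm",
    "neural_network",
    ENSEMBLE_FAMILY,
]


class FeatureSchemaError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Aligned feature rows, optional labels, and variant keys."""

    X: pd.DataFrame
    y: np.ndarray | None  # 1 = pathogenic, 0 = benign
    keys: list[str]

    def __post_init__(self) -> None:
        if list(self.X.columns) != FEATURE_COLUMNS:
            raise FeatureSchemaError("feature matrix columns out of schema order")
        if self.y is not None and len(self.y) != len(self.X):
            raise ValueError("labels not aligned with rows")

    def __len__(self) -> int:
        return len(self.X)


def assemble_features(
    features: pd.DataFrame,
    labels: Mapping[str, str] | None = None,
    dual_match: Mapping[str, bool] | None = None,
    key_column: str = "variant_key",
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Build (labelled, unlabelled) matrices from a feature table.

    Rows without a matched dual-genome amino-acid consequence (when
    ``dual_match`` is given) and rows with all 13 features missing are
    excluded.  Labels come from harmonised curated verdicts: variants
    harmonised deleterious become ``pathogenic`` and harmonised benign
    become ``benign``; everything else is unlabelled.  Per-feature
    missing rates are logged.
    """
    missing_cols = [c for c in [key_column, *FEATURE_COLUMNS] if c not in features.columns]
    if missing_cols:
        raise FeatureSchemaError(f"feature table lacks columns: {missing_cols}")
    frame = features.copy()
    if dual_match is not None:
        keep = frame[key_column].map(lambda k: bool(dual_match.get(k, False)))
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("excluded %d variants without dual-genome consequence match", n_drop)
        frame = frame[keep]
    X = frame[FEATURE_COLUMNS].astype(float)
    all_missing = X.isna().all(axis=1)
    if all_missing.any():
        logger.info("excluded %d variants with all features missing", int(all_missing.sum()))
        frame, X = frame[~all_missing.to_numpy()], X[~all_missing.to_numpy()]
    for col in FEATURE_COLUMNS:
        rate = float(X[col].isna().mean()) if len(X) else 0.0
        logger.debug("feature %s missing rate %.3f", col, rate)

    keys = frame[key_column].astype(str).tolist()
    verdicts = [labels.get(k) if labels else None for k in keys]
    y = np.array(
        [
            1 if v == "deleterious" else (0 if v == "benign" else -1)
            for v in verdicts
        ]
    )
    labelled_mask = y >= 0
    labelled = FeatureMatrix(
        X=X[labelled_mask].reset_index(drop=True),
        y=y[labelled_mask],
        keys=[k for k, m in zip(keys, labelled_mask) if m],
    )
    unlabelled = FeatureMatrix(
        X=X[~labelled_mask].reset_index(drop=True),
        y=None,
        keys=[k for k, m in zip(keys, labelled_mask) if not m],
    )
    return labelled, unlabelled


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties 0.5)."""
    return float(roc_auc_score(y_true, scores))


class _MeanEnsemble:
    """Unweighted mean of the calibrated scores of fitted base models."""

    def __init__(self, models: Sequence):
        self.models = list(models)

    def predict_proba(self, X) -> np.ndarray:
        probs = np.mean([m.predict_proba(X)[:, 1] for m in self.models], axis=0)
        return np.column_stack([1.0 - probs, probs])


def _family_factories(
    families: Sequence[str],
    extra: Mapping[str, Callable[[int], object]] | None,
) -> dict[str, Callable[[int], object] | None]:
    registry = _default_families()
    if extra:
        registry.update(extra)
    out: dict[str, Callable[[int], object] | None] = {}
    for name in families:
        if name == ENSEMBLE_FAMILY:
            out[name] = None
        elif name in registry:
            out[name] = registry[name]
        else:
            raise ValueError(f"unregistered model family: {name}")
    return out


def crossval_family_scores(
    X: pd.DataFrame,
    y: np.ndarray,
    families: Sequence[str],
    k: int = 5,
    seed: int = 0,
    extra_families: Mapping[str, Callable[[int], object]] | None = None,
) -> dict[str, list[float]]:
    """Per-fold held-out AUCs for every family on shared stratified folds.

    The ensemble family's fold score is the mean of the base families'
    held-out probabilities on that fold, so no model is refit for it.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if k > counts.min():
        raise ValueError("k exceeds the minority class count; stratification impossible")
    factories = _family_factories(families, extra_families)
    base_names = [f for f in families if f != ENSEMBLE_FAMILY]
    want_ensemble = ENSEMBLE_FAMILY in families
    if want_ensemble and not base_names:
        raise ValueError("ensemble requires at least one base family")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs: dict[str, list[float]] = {f: [] for f in families}
    for train_idx, test_idx in skf.split(X, y):
        X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        fold_probs = []
        for name in base_names:
            model = factories[name](seed)
            model.fit(X_tr, y_tr)
            p = model.predict_proba(X_te)[:, 1]
            fold_aucs[name].append(auc_score(y_te, p))
            fold_probs.append(p)
        if want_ensemble:
            fold_aucs[ENSEMBLE_FAMILY].append(auc_score(y_te, np.mean(fold_probs, axis=0)))
    return fold_aucs


def crossval_auc(
    X: pd.DataFrame,
    y: np.ndarray,
    family: str,
    k: int = 5,
    seed: int = 0,
    extra_families: Mapping[str, Callable[[int], object]] | None = None,
) -> tuple[list[float], float]:
    """Per-fold AUCs and their mean for a single family."""
    families = [family] if family != ENSEMBLE_FAMILY else DEFAULT_FAMILY_ORDER
    scores = crossval_family_scores(X, y, families, k=k, seed=seed, extra_families=extra_families)
    folds = scores[family]
    return folds, float(np.mean(folds))


@dataclass
class ScoreModel:
    """A fitted scoring family with its provenance fingerprint."""

    family: str
    estimator: object
    cv_auc: float
    cv_fold_aucs: list[float]
    seed: int
    k: int
    n_training: int

    def score(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != FEATURE_COLUMNS:
            raise FeatureSchemaError("scoring matrix columns out of schema order")
        if len(X) == 0:
            return np.zeros(0)
        return self.estimator.predict_proba(X)[:, 1]


class HMScoreModel:
    """Integrative pathogenicity scorer over the 13-feature matrix."""

    def __init__(
        self,
        matrix: FeatureMatrix,
        families: Sequence[str] | None = None,
        extra_families: Mapping[str, Callable[[int], object]] | None = None,
    ):
        if matrix.y is None:
            raise ValueError("training requires a labelled matrix")
        if len(set(families or DEFAULT_FAMILY_ORDER)) < 2:
            raise ValueError("need at least two registered families to benchmark")
        self.matrix = matrix
        self.families = list(families or DEFAULT_FAMILY_ORDER)
        self.extra_families = dict(extra_families or {})

    def fit(self, k: int = 5, seed: int = 0) -> "HMScoreResults":
        X, y = self.matrix.X, self.matrix.y
        fold_aucs = crossval_family_scores(
            X, y, self.families, k=k, seed=seed, extra_families=self.extra_families
        )
        leaderboard = pd.DataFrame(
            {
                "family": self.families,
                "mean_cv_auc": [float(np.mean(fold_aucs[f])) for f in self.families],
            }
        )
        order = np.argsort(-leaderboard["mean_cv_auc"].to_numpy(), kind="stable")
        leaderboard = leaderboard.iloc[order].reset_index(drop=True)
        best_family = str(leaderboard.at[0, "family"])

        factories = _family_factories(self.families, self.extra_families)
        base_names = [f for f in self.families if f != ENSEMBLE_FAMILY]
        fitted_bases = {}
        needed = base_names if best_family == ENSEMBLE_FAMILY else [best_family]
        for name in needed:
            est = factories[name](seed)
            est.fit(X, y)
            fitted_bases[name] = est
        estimator = (
            _MeanEnsemble([fitted_bases[n] for n in base_names])
            if best_family == ENSEMBLE_FAMILY
            else fitted_bases[best_family]
        )
        model = ScoreModel(
            family=best_family,
            estimator=estimator,
            cv_auc=float(leaderboard.at[0, "mean_cv_auc"]),
            cv_fold_aucs=[float(a) for a in fold_aucs[best_family]],
            seed=seed,
            k=k,
            n_training=len(X),
        )
        return HMScoreResults(model=model, leaderboard=leaderboard, fold_aucs=fold_aucs)


@dataclass
class HMScoreResults:
    model: ScoreModel
    leaderboard: pd.DataFrame
    fold_aucs: dict[str, list[float]]

    @property
    def best_family(self) -> str:
        return self.model.family

    @property
    def cv_auc(self) -> float:
        return self.model.cv_auc

    def score(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.score(X)

    def summary(self) -> str:
        lines = [
            "Integrative pathogenicity score",
            f"  training variants : {self.model.n_training}",
            f"  cross-validation  : {self.model.k}-fold, seed {self.model.seed}",
            f"  best family       : {self.model.family} (mean CV AUC {self.model.cv_auc:.3f})",
            "  leaderboard:",
        ]
        for row in self.leaderboard.itertuples(index=False):
            lines.append(f"    {row.family:<20s} {row.mean_cv_auc:.3f}")
        return "\n".join(lines)


def train_hm_model(
    matrix: FeatureMatrix,
    families: Sequence[str] | None = None,
    k: int = 5,
    seed: int = 0,
    extra_families: Mapping[str, Callable[[int], object]] | None = None,
) -> HMScoreResults:
    """Benchmark the families by CV AUC and refit the winner on all data."""
    return HMScoreModel(matrix, families=families, extra_families=extra_families).fit(
        k=k, seed=seed
    )


@dataclass
class ScoredVariant:
    variant_key: str
    hm_score: float
    percentile: float
    flagged: bool = False


def score_variants(results: HMScoreResults | ScoreModel, matrix: FeatureMatrix) -> pd.DataFrame:
    """Score a matrix; percentile is the empirical CDF of the scored set."""
    model = results.model if isinstance(results, HMScoreResults) else results
    scores = model.score(matrix.X)
    if len(scores) == 0:
        return pd.DataFrame(columns=["variant_key", "hm_score", "percentile"])
    # empirical CDF with ties sharing the proportion <= score
    cdf = np.searchsorted(np.sort(scores), scores, side="right") / len(scores)
    return pd.DataFrame(
        {"variant_key": matrix.keys, "hm_score": scores, "percentile": cdf}
    )


def top_percentile_threshold(
    scores: Sequence[float] | np.ndarray, fraction: float = 0.01
) -> tuple[float, np.ndarray]:
    """Smallest score whose upper tail proportion is <= fraction.

    Returns (threshold, flag mask of scores >= threshold).  Ties at the
    threshold are all flagged, so the flagged set may exceed the
    nominal fraction; if even the maximum score is too common, every
    tie at the maximum is flagged.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one score")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    unique_desc = np.unique(s)[::-1]
    n = s.size
    threshold = unique_desc[0]
    for v in unique_desc:
        if np.sum(s >= v) / n <= fraction:
            threshold = v
        else:
            break
    return float(threshold), s >= threshold
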