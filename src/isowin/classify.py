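"""Per-gene supervised classification of group labels from window features.

For each gene the retained samples are split 80/20 (stratified), features
are filtered for near-zero variance and z-scaled using training statistics
only, a model is tuned by repeated stratified cross-validation (10-fold,
5 repeats) over a hyperparameter grid, refit on the full training set, and
scored on the held-out test set.  The reported P value is the one-sided
exact binomial tail probability of the observed number of correct test-set
predictions under Binomial(n_test, NIR), where the no-information rate (NIR)
is the majority-class share of the test set.  A small P value means the
gene's windowed read distribution discriminates the groups better than
always guessing the majority class — the signature of differential isoform
usage.

Model families: baseline logistic regression, elastic-net penalized logistic
regression, random forest, and gradient boosting (xgboost).  Variable
importance is model-based: |z| statistics (logistic), |coefficients| on the
standardized scale (elastic net), mean impurity decrease (random forest),
and total split gain (gradient boosting), each rescaled to [0, 100] within
the gene.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

logger = logging.getLogger(__name__)

MODEL_TYPES = ("logistic", "elastic_net", "random_forest", "gradient_boosting")

# Default tuning grids.  The small presets keep desk-scale runtime for large
# cohorts; both are plain lists of keyword dicts and fully user-overridable.
DEFAULT_GRIDS: dict[str, list[dict[str, Any]]] = {
    "logistic": [{}],
    "elastic_net": [
        {"l1_ratio": round(a, 1), "C": float(c)}
        for a in np.arange(0.1, 1.01, 0.1)
        for c in np.logspace(-2, 2, 10)
    ],
    "random_forest": [
        {"max_features": mf, "n_estimators": 500} for mf in ("sqrt", 0.333, 1.0)
    ],
    "gradient_boosting": [
        {"max_depth": d, "learning_rate": lr, "n_estimators": n}
        for d in (1, 2, 3)
        for lr in (0.3, 0.1)
        for n in (50, 100, 150)
    ],
}

SMALL_GRIDS: dict[str, list[dict[str, Any]]] = {
    "logistic": [{}],
    "elastic_net": [
        {"l1_ratio": a, "C": c} for a in (0.1, 0.5, 1.0) for c in (0.1, 1.0)
    ],
    "random_forest": [{"max_features": "sqrt", "n_estimators": 200}],
    "gradient_boosting": [
        {"max_depth": d, "learning_rate": 0.3, "n_estimators": 60} for d in (1, 2)
    ],
}


@dataclass
class SplitSpec:
    seed: int
    train_ids: list[str]
    test_ids: list[str]


@dataclass
class PreprocessState:
    """Training-derived feature statistics; applied unchanged to test data."""

    kept_windows: list[int]  # column indices surviving the NZV filter
    means: np.ndarray
    sds: np.ndarray


@dataclass
class ModelSpec:
    model_type: str
    grid: Optional[list[dict[str, Any]]] = None
    cv_folds: int = 10
    cv_repeats: int = 5

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"unknown model type {self.model_type!r}")
        if self.grid is None:
            self.grid = DEFAULT_GRIDS[self.model_type]
        if not self.grid:
            raise ValueError("empty hyperparameter grid")


@dataclass
class FittedModel:
    model_type: str
    model: Any
    params: dict[str, Any]
    cv_accuracy: float
    classes: np.ndarray  # label strings, index = encoded class
    majority_class: int  # encoded majority class of the training set


@dataclass
class GeneFitResult:
    gene_id: str
    model_type: str
    params: dict[str, Any]
    n_train: int
    n_test: int
    cv_accuracy: float
    test_accuracy: float
    nir: float
    p_value: float
    kept_window_names: list[str]
    importance: np.ndarray  # scaled to [0, 100]
    raw_importance: np.ndarray


class UntestableGene(Exception):
    """Raised when a gene cannot be evaluated (no informative windows, or a
    class too small to appear in both partitions)."""


# ---------------------------------------------------------------------------
# splitting and preprocessing


def split_samples(
    sample_ids: Sequence[str],
    labels: Sequence[str],
    frac: float = 0.8,
    seed: int = 0,
) -> SplitSpec:
    """Stratified random train/test split; the per-class training count is
    round-half-up of ``frac`` times the class size."""
    sample_ids = list(sample_ids)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise UntestableGene(
                f"class {cls!r} has {len(idx)} sample(s); cannot appear in both partitions"
            )
        n_train = int(math.floor(frac * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(len(idx))
        train.extend(sample_ids[i] for i in idx[perm[:n_train]])
        test.extend(sample_ids[i] for i in idx[perm[n_train:]])
    return SplitSpec(seed=seed, train_ids=sorted(train), test_ids=sorted(test))


def near_zero_variance(
    X: np.ndarray, freq_cut: float = 95.0 / 5.0, unique_cut: float = 10.0
) -> np.ndarray:
    """Boolean mask of columns to KEEP.

    A column is dropped when it is constant, or when the ratio of the most
    common value's frequency to the second most common exceeds ``freq_cut``
    AND the percentage of unique values is below ``unique_cut`` (the
    conventional defaults: 95/5 and 10%).
    """
    n = X.shape[0]
    keep = np.ones(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        vals, counts = np.unique(X[:, j], return_counts=True)
        if len(vals) == 1:
            keep[j] = False
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        pct_unique = 100.0 * len(vals) / n
        if freq_ratio > freq_cut and pct_unique < unique_cut:
            keep[j] = False
    return keep


def preprocess_features(
    X: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[PreprocessState, np.ndarray, np.ndarray]:
    """Near-zero-variance filter and z-scaling, fit on training rows only."""
    keep = near_zero_variance(X[train_idx])
    if not keep.any():
        raise UntestableGene("all windows removed by the near-zero-variance filter")
    kept = np.flatnonzero(keep)
    Xtr = X[np.ix_(train_idx, kept)]
    means = Xtr.mean(axis=0)
    sds = Xtr.std(axis=0, ddof=1)
    sds = np.where(sds > 0, sds, 1.0)
    state = PreprocessState(kept_windows=kept.tolist(), means=means, sds=sds)
    Xtr_z = (Xtr - means) / sds
    Xte_z = (X[np.ix_(test_idx, kept)] - means) / sds
    return state, Xtr_z, Xte_z


# ---------------------------------------------------------------------------
# model fitting


def _make_estimator(model_type: str, params: dict[str, Any], seed: int):
    if model_type == "logistic":
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000, **params)
    if model_type == "elastic_net":
        # l1_ratio in (0,1] with saga gives the elastic-net penalty
        return LogisticRegression(solver="saga", max_iter=5000, tol=1e-3, **params)
    if model_type == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if model_type == "gradient_boosting":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            max_bin=64,
            verbosity=0,
            **params,
        )
    raise ValueError(model_type)


def tune_and_fit(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec, seed: int = 0
) -> FittedModel:
    """Grid search by repeated stratified CV on mean accuracy, then refit the
    best grid point on the full training set.  Deterministic given the seed;
    ties between grid points go to the earlier one.  With a single-point
    grid the CV stage is skipped (cv_accuracy = NaN)."""
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise UntestableGene("training data contains a single class")
    cv_acc = float("nan")
    grid = spec.grid
    best = grid[0]
    if len(grid) > 1:
        rskf = RepeatedStratifiedKFold(
            n_splits=spec.cv_folds, n_repeats=spec.cv_repeats, random_state=seed
        )
        splits = list(rskf.split(X, y_enc))
        mean_accs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for params in grid:
                accs = []
                for tr, va in splits:
                    est = _make_estimator(spec.model_type, params, seed)
                    est.fit(X[tr], y_enc[tr])
                    accs.append(float(np.mean(est.predict(X[va]) == y_enc[va])))
                mean_accs.append(float(np.mean(accs)))
        best_i = int(np.argmax(mean_accs))
        best = grid[best_i]
        cv_acc = mean_accs[best_i]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = _make_estimator(spec.model_type, best, seed)
        model.fit(X, y_enc)
    majority = int(np.argmax(np.bincount(y_enc)))
    return FittedModel(spec.model_type, model, dict(best), cv_acc, classes, majority)


def predict_labels(fitted: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predict encoded labels; exact probability ties go to the training
    majority class."""
    proba = fitted.model.predict_proba(X)
    pred = np.argmax(proba, axis=1)
    ties = np.isclose(proba[:, 0], proba[:, 1], rtol=0, atol=1e-12)
    pred[ties] = fitted.majority_class
    return pred


def binomial_accuracy_pvalue(k: int, n: int, nir: float) -> float:
    """One-sided exact binomial tail P(X >= k), X ~ Binomial(n, nir)."""
    return float(stats.binom.sf(k - 1, n, nir))


def score_model(
    fitted: FittedModel, X_test: np.ndarray, y_test: np.ndarray
) -> tuple[float, float, float]:
    """Held-out accuracy, no-information rate, and exact binomial P value."""
    if len(y_test) == 0:
        raise ValueError("empty test set")
    _, y_enc = np.unique(np.concatenate([fitted.classes, y_test]), return_inverse=True)
    y_enc = y_enc[len(fitted.classes):]
    pred = predict_labels(fitted, X_test)
    k = int(np.sum(pred == y_enc))
    n = len(y_enc)
    nir = float(np.max(np.bincount(y_enc, minlength=len(fitted.classes))) / n)
    acc = k / n
    return acc, nir, binomial_accuracy_pvalue(k, n, nir)


def extract_importance(
    fitted: FittedModel,
    X_train: Optional[np.ndarray] = None,
    y_train: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-based per-window importance, raw and rescaled to [0, 100].

    logistic: |z| of each coefficient (Wald, from the observed information
    matrix; falls back to |coefficient| if the information matrix is
    degenerate, e.g. under perfect separation); elastic net: |coefficient|;
    random forest: mean impurity decrease; gradient boosting: total gain
    (features never used in a split score 0).
    """
    mt = fitted.model_type
    model = fitted.model
    if mt == "logistic":
        raw = np.abs(model.coef_.ravel())
        if X_train is not None:
            z = _logistic_z(model, X_train)
            if z is not None:
                raw = z
    elif mt == "elastic_net":
        raw = np.abs(model.coef_.ravel())
    elif mt == "random_forest":
        raw = model.feature_importances_.copy()
    elif mt == "gradient_boosting":
        booster = model.get_booster()
        gain = booster.get_score(importance_type="total_gain")
        raw = np.array([gain.get(f"f{i}", 0.0) for i in range(model.n_features_in_)])
    else:
        raise ValueError(mt)
    mx = raw.max()
    scaled = raw / mx * 100.0 if mx > 0 else np.zeros_like(raw)
    return raw, scaled


def _logistic_z(model: LogisticRegression, X: np.ndarray) -> Optional[np.ndarray]:
    """Wald |z| statistics from the observed information of the fitted
    logistic model (intercept included, then discarded)."""
    Xd = np.column_stack([np.ones(len(X)), X])
    beta = np.concatenate([model.intercept_, model.coef_.ravel()])
    eta = Xd @ beta
    p = stats.logistic.cdf(eta)
    W = p * (1 - p)
    info = (Xd * W[:, None]).T @ Xd
    try:
        cov = np.linalg.pinv(info)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)[1:]
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        return None
    z = np.abs(model.coef_.ravel()) / np.sqrt(var)
    return z if np.all(np.isfinite(z)) else None


# ---------------------------------------------------------------------------
# per-gene orchestration


def gene_seed(base_seed: int, gene_id: str) -> int:
    """Stable per-gene seed below 2**31, independent of gene order."""
    h = np.random.SeedSequence([base_seed] + [ord(c) for c in gene_id])
    return int(h.generate_state(1)[0] % 2**31)


def fit_gene(
    fm,
    spec: ModelSpec,
    seed: int = 0,
    frac: float = 0.8,
    permute_train_rng: Optional[np.random.Generator] = None,
) -> GeneFitResult:
    """Run the full per-gene pipeline on a FeatureMatrix.

    ``permute_train_rng``, if given, shuffles the *training* labels before
    fitting (the test labels stay untouched) — the permutation-null branch
    used for FDR estimation.
    """
    sseed = gene_seed(seed, fm.gene_id)
    split = split_samples(fm.samples, fm.labels, frac=frac, seed=sseed)
    pos = {s: i for i, s in enumerate(fm.samples)}
    train_idx = np.array([pos[s] for s in split.train_ids])
    test_idx = np.array([pos[s] for s in split.test_ids])
    state, Xtr, Xte = preprocess_features(fm.values, train_idx, test_idx)
    y_tr = np.asarray(fm.labels)[train_idx]
    y_te = np.asarray(fm.labels)[test_idx]
    if permute_train_rng is not None:
        y_tr = permute_train_rng.permutation(y_tr)
        if len(np.unique(y_tr)) < 2:  # cannot happen for a valid split
            raise UntestableGene("permutation produced a single-class training set")
    fitted = tune_and_fit(Xtr, y_tr, spec, seed=sseed)
    acc, nir, p = score_model(fitted, Xte, y_te)
    raw, scaled = extract_importance(fitted, Xtr, y_tr)
    names = [fm.windows[j].name for j in state.kept_windows]
    return GeneFitResult(
        gene_id=fm.gene_id,
        model_type=spec.model_type,
        params=fitted.params,
        n_train=len(train_idx),
        n_test=len(test_idx),
        cv_accuracy=fitted.cv_accuracy,
        test_accuracy=acc,
        nir=nir,
        p_value=p,
        kept_window_names=names,
        importance=scaled,
        raw_importance=raw,
    )


def results_to_frame(results: Sequence[GeneFitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "model_type": [r.model_type for r in results],
            "n_train": [r.n_train for r in results],
            "n_test": [r.n_test for r in results],
            "nir": [r.nir for r in results],
            "cv_accuracy": [r.cv_accuracy for r in results],
            "test_accuracy": [r.test_accuracy for r in results],
            "p_value": [r.p_value for r in results],
            "params": [json.dumps(r.params, sort_keys=True) for r in results],
        }
    )


def importance_to_frame(results: Sequence[GeneFitResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for name, raw, scaled in zip(r.kept_window_names, r.raw_importance, r.importance):
            rows.append((r.gene_id, r.model_type, name, raw, scaled))
    return pd.DataFrame(
        rows, columns=["gene_id", "model_type", "window", "raw_importance", "importance"]
    )
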