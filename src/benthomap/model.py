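"""Per-realm community classifiers over the cell grid.

A random-forest multiclass model predicts community tokens (HUB levels
4-6) from per-cell predictors.  The contract: a 70/30 random split,
hyperparameters (tree count, predictors per split) tuned to the lowest
out-of-bag error, imbalance handling applied to the training partition
only, and evaluation on the untouched test partition with overall
accuracy, an exact binomial confidence interval, Cohen's kappa and the
mean-pairwise (Hand-Till) multiclass AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .synthetic import PREDICTOR_LAYERS

__all__ = [
    "ModelConfig",
    "FitResult",
    "PredictionGrid",
    "build_feature_matrix",
    "fit",
    "evaluate",
    "confusion_matrix",
    "accuracy_ci",
    "cohens_kappa",
    "hand_till_auc",
    "predict_grid",
    "ENDO_PREDICTORS",
    "EPI_PREDICTORS",
]

# Slope, PAR and photic zonation enter the epibenthos model only.
ENDO_PREDICTORS = [p for p in PREDICTOR_LAYERS if p != "par"]
EPI_PREDICTORS = PREDICTOR_LAYERS + ["photic"]


@dataclass(frozen=True)
class ModelConfig:
    realm: str = "endo"  # "endo" or "epi"
    train_fraction: float = 0.70
    n_trees_grid: tuple[int, ...] = (250, 500, 1000)
    mtry_offsets: tuple[int, ...] = (-1, 0, 1)  # around floor(sqrt(p))
    imbalance: str = "none"  # none | downsample | upsample | balanced | smote
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not self.n_trees_grid or not self.mtry_offsets:
            raise ValueError("tuning grids must be non-empty")
        if self.imbalance not in ("none", "downsample", "upsample", "balanced", "smote"):
            raise ValueError(f"unknown imbalance strategy {self.imbalance!r}")
        if self.realm not in ("endo", "epi"):
            raise ValueError("realm must be 'endo' or 'epi'")


@dataclass
class FitResult:
    confusion: pd.DataFrame
    accuracy: float
    ci_low: float
    ci_high: float
    auc: float | None
    kappa: float | None
    oob_error: float
    importance: pd.Series  # descending
    n_trees: int
    mtry: int
    classes: list[str]
    model: RandomForestClassifier | None = None
    feature_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ci_95": [self.ci_low, self.ci_high],
            "auc": self.auc,
            "kappa": self.kappa,
            "oob_error": self.oob_error,
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "classes": self.classes,
            "importance": self.importance.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def build_feature_matrix(
    stations: pd.DataFrame,
    environment: dict[str, np.ndarray],
    sediment: np.ndarray,
    realm: str,
    photic: np.ndarray | None = None,
    hard: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """One row per labelled station: predictors sampled at the station's
    cell (centre-point attribution), sediment as a categorical column.

    ``stations`` needs ``row``, ``col`` and ``label`` columns (one row
    per station).  For the epi realm, only stations on hard-substrate
    dominated cells enter when ``hard`` is given.
    """
    predictors = ENDO_PREDICTORS if realm == "endo" else EPI_PREDICTORS
    if stations.empty:
        cols = [p for p in predictors if p != "photic"] + (
            ["photic"] if realm == "epi" else []
        ) + ["sediment"]
        return pd.DataFrame(columns=cols), pd.Series(dtype=object)

    rows = stations["row"].to_numpy()
    cols_ = stations["col"].to_numpy()
    keep = np.ones(len(stations), dtype=bool)
    if realm == "epi" and hard is not None:
        keep &= hard[rows, cols_]
    data = {}
    for name in predictors:
        if name == "photic":
            if photic is None:
                raise ValueError("epi realm requires the photic grid")
            data[name] = photic[rows, cols_].astype(int)
        else:
            data[name] = environment[name][rows, cols_]
    data["sediment"] = sediment[rows, cols_].astype(str)
    X = pd.DataFrame(data, index=stations.index)[keep]
    y = stations["label"][keep]
    return X.reset_index(drop=True), y.reset_index(drop=True)


def _encode(X: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """One-hot encode categorical columns, aligned to ``columns`` if given."""
    enc = pd.get_dummies(X, columns=[c for c in ("sediment",) if c in X.columns])
    if columns is not None:
        enc = enc.reindex(columns=columns, fill_value=0)
    return enc.astype(float)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred, classes=None) -> pd.DataFrame:
    """Rows = true class, columns = predicted class."""
    y_true = pd.Series(list(y_true))
    y_pred = pd.Series(list(y_pred))
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def accuracy_ci(successes: int, total: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    if total <= 0:
        raise ValueError("total must be positive")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, total - successes + 1)
    hi = 1.0 if successes == total else stats.beta.ppf(1 - alpha / 2, successes + 1, total - successes)
    return float(lo), float(hi)


def cohens_kappa(confusion: pd.DataFrame | np.ndarray) -> float | None:
    """Chance-corrected agreement from a square confusion matrix.

    Returns None (with the caller expected to report NA) when expected
    agreement is 1, i.e. all mass sits in a single row/column pair.
    """
    mat = np.asarray(confusion, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(mat < 0):
        raise ValueError("confusion matrix must be non-negative")
    total = mat.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(mat) / total
    p_e = float((mat.sum(axis=0) / total) @ (mat.sum(axis=1) / total))
    if p_e >= 1.0 - 1e-12:
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def _pairwise_auc(score_i: np.ndarray, is_i: np.ndarray) -> float:
    """P(score of a class-i sample > score of a non-i sample), ties 0.5."""
    ranks = stats.rankdata(score_i)
    n_i = int(is_i.sum())
    n_j = len(is_i) - n_i
    if n_i == 0 or n_j == 0:
        return np.nan
    return (ranks[is_i].sum() - n_i * (n_i + 1) / 2.0) / (n_i * n_j)


def hand_till_auc(y_true, proba: np.ndarray, classes) -> float | None:
    """Multiclass AUC as the unweighted mean of all pairwise class AUCs.

    For each unordered class pair (i, j), samples of the two classes are
    compared on the class-i probability and on the class-j probability;
    the pair's AUC is the average of the two directions.
    """
    y_true = np.asarray(list(y_true))
    classes = list(classes)
    idx = {c: k for k, c in enumerate(classes)}
    present = [c for c in classes if (y_true == c).any()]
    if len(present) < 2:
        return None
    aucs = []
    for a in range(len(present)):
        for b in range(a + 1, len(present)):
            ci, cj = present[a], present[b]
            sel = (y_true == ci) | (y_true == cj)
            is_i = y_true[sel] == ci
            a_ij = _pairwise_auc(proba[sel, idx[ci]], is_i)
            a_ji = _pairwise_auc(proba[sel, idx[cj]], ~is_i)
            aucs.append((a_ij + a_ji) / 2.0)
    return float(np.mean(aucs))


def evaluate(
    confusion: pd.DataFrame,
    y_true=None,
    proba: np.ndarray | None = None,
    classes=None,
) -> dict:
    """Accuracy, exact 95% CI, kappa, and (when probabilities are
    supplied) Hand-Till AUC from a test-set confusion matrix."""
    mat = np.asarray(confusion, dtype=float)
    total = int(mat.sum())
    successes = int(np.trace(mat))
    acc = successes / total
    lo, hi = accuracy_ci(successes, total)
    kappa = cohens_kappa(mat)
    auc = None
    if proba is not None and y_true is not None and classes is not None:
        auc = hand_till_auc(y_true, proba, classes)
    return {"accuracy": acc, "ci_low": lo, "ci_high": hi, "kappa": kappa, "auc": auc}


# ---------------------------------------------------------------------------
# Imbalance handling
# ---------------------------------------------------------------------------

def _resample_train(
    X: pd.DataFrame, y: pd.Series, strategy: str, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    if strategy in ("none", "balanced"):
        return X, y
    counts = y.value_counts()
    if strategy == "downsample":
        n_target = counts.min()
        parts = []
        for cls in counts.index:
            idx = np.flatnonzero((y == cls).to_numpy())
            take = rng.choice(idx, size=n_target, replace=False)
            parts.append(take)
        sel = np.concatenate(parts)
        return X.iloc[sel].reset_index(drop=True), y.iloc[sel].reset_index(drop=True)
    if strategy == "upsample":
        n_target = counts.max()
        parts = []
        for cls in counts.index:
            idx = np.flatnonzero((y == cls).to_numpy())
            take = rng.choice(idx, size=n_target, replace=True)
            parts.append(take)
        sel = np.concatenate(parts)
        return X.iloc[sel].reset_index(drop=True), y.iloc[sel].reset_index(drop=True)
    if strategy == "smote":
        return _smote(X, y, rng)
    raise AssertionError(strategy)


def _smote(
    X: pd.DataFrame, y: pd.Series, rng: np.random.Generator, k: int = 5
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic minority oversampling on continuous columns; one-hot
    (categorical) columns take the majority value among the neighbours."""
    counts = y.value_counts()
    n_target = counts.max()
    cont = [c for c in X.columns if not c.startswith("sediment")]
    cat = [c for c in X.columns if c.startswith("sediment")]
    new_X, new_y = [X], [y]
    for cls, n_cls in counts.items():
        deficit = n_target - n_cls
        if deficit <= 0:
            continue
        Xc = X[y == cls].reset_index(drop=True)
        if len(Xc) == 1:
            reps = Xc.iloc[np.zeros(deficit, dtype=int)].reset_index(drop=True)
            new_X.append(reps)
            new_y.append(pd.Series([cls] * deficit))
            continue
        k_eff = min(k, len(Xc) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc[cont].to_numpy())
        _, neigh = nn.kneighbors(Xc[cont].to_numpy())
        rows = []
        for _ in range(deficit):
            i = int(rng.integers(len(Xc)))
            j = int(neigh[i, 1 + rng.integers(k_eff)])
            lam = rng.random()
            row = {}
            for c in cont:
                row[c] = Xc.at[i, c] + lam * (Xc.at[j, c] - Xc.at[i, c])
            group = Xc.iloc[neigh[i]]
            for c in cat:
                row[c] = float(group[c].mean() >= 0.5)
            rows.append(row)
        new_X.append(pd.DataFrame(rows, columns=X.columns))
        new_y.append(pd.Series([cls] * deficit))
    Xr = pd.concat(new_X, ignore_index=True)
    yr = pd.concat(new_y, ignore_index=True)
    return Xr, yr


# ---------------------------------------------------------------------------
# Fitting and prediction
# ---------------------------------------------------------------------------

def fit(config: ModelConfig, features: pd.DataFrame, response: pd.Series) -> FitResult:
    """Train, tune by OOB error, and evaluate on the held-out 30 %."""
    y = pd.Series(list(response), dtype=object)
    counts = y.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need at least 2 classes with at least 2 rows each")

    X_enc = _encode(features)
    feature_columns = list(X_enc.columns)
    stratify = y if counts.min() >= 2 else None
    X_train, X_test, y_train, y_test = train_test_split(
        X_enc, y,
        train_size=config.train_fraction,
        random_state=config.seed,
        stratify=stratify,
    )
    missing = set(y) - set(y_train)
    if missing:
        raise ValueError(f"class(es) {sorted(missing)} absent from the training split")

    rng = np.random.default_rng(config.seed)
    X_fit, y_fit = _resample_train(
        X_train.reset_index(drop=True), y_train.reset_index(drop=True),
        config.imbalance, rng,
    )

    p = X_enc.shape[1]
    base_mtry = max(1, int(np.floor(np.sqrt(p))))
    mtry_grid = sorted({max(1, min(p, base_mtry + o)) for o in config.mtry_offsets})

    best = None
    for n_trees in config.n_trees_grid:
        for mtry in mtry_grid:
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features=mtry,
                oob_score=True,
                random_state=config.seed,
                n_jobs=1,
                class_weight="balanced_subsample" if config.imbalance == "balanced" else None,
            )
            rf.fit(X_fit.to_numpy(), y_fit.to_numpy())
            oob_err = 1.0 - rf.oob_score_
            key = (oob_err, n_trees, mtry)
            if best is None or key < best[0]:
                best = (key, rf, n_trees, mtry)
    _, rf, n_trees, mtry = best
    oob_error = best[0][0]

    classes = list(rf.classes_)
    y_pred = rf.predict(X_test.to_numpy())
    proba = rf.predict_proba(X_test.to_numpy())
    conf = confusion_matrix(y_test, y_pred, classes=sorted(set(y)))
    metrics = evaluate(conf, y_true=y_test, proba=proba, classes=classes)

    raw_imp = pd.Series(rf.feature_importances_, index=feature_columns)
    agg = {}
    for name, value in raw_imp.items():
        key = "sediment" if name.startswith("sediment_") else name
        agg[key] = agg.get(key, 0.0) + value
    importance = pd.Series(agg).sort_values(ascending=False)

    return FitResult(
        confusion=conf,
        accuracy=metrics["accuracy"],
        ci_low=metrics["ci_low"],
        ci_high=metrics["ci_high"],
        auc=metrics["auc"],
        kappa=metrics["kappa"],
        oob_error=oob_error,
        importance=importance,
        n_trees=n_trees,
        mtry=mtry,
        classes=classes,
        model=rf,
        feature_columns=feature_columns,
    )


@dataclass
class PredictionGrid:
    tokens: np.ndarray  # object array, None where not predicted
    probability: np.ndarray  # float array, nan where not predicted

    def __post_init__(self):
        has_token = np.vectorize(lambda t: t is not None)(self.tokens)
        if np.any(has_token & ~np.isfinite(self.probability)):
            raise ValueError("every predicted token needs a probability")


def predict_grid(
    result: FitResult,
    environment: dict[str, np.ndarray],
    sediment: np.ndarray,
    realm: str,
    photic: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> PredictionGrid:
    """Predict a community token and its vote share for every grid cell.

    Cells with any missing predictor, or outside ``mask``, are NA.
    """
    shape = sediment.shape
    predictors = ENDO_PREDICTORS if realm == "endo" else EPI_PREDICTORS
    data = {}
    valid = np.ones(shape, dtype=bool)
    for name in predictors:
        if name == "photic":
            layer = photic.astype(float)
        else:
            layer = environment[name]
        valid &= np.isfinite(layer)
        data[name] = layer.ravel()
    sed_flat = sediment.astype(str).ravel()
    valid &= (sediment != None).astype(bool)  # noqa: E711  (object grids)
    if mask is not None:
        valid &= mask
    flat_valid = valid.ravel()

    tokens = np.full(shape, None, dtype=object)
    probability = np.full(shape, np.nan)
    if flat_valid.any():
        X = pd.DataFrame({k: v[flat_valid] for k, v in data.items()})
        X["sediment"] = sed_flat[flat_valid]
        X_enc = _encode(X, columns=result.feature_columns)
        proba = result.model.predict_proba(X_enc.to_numpy())
        winner = np.argmax(proba, axis=1)
        tok = np.asarray(result.model.classes_)[winner]
        tokens.ravel()[np.flatnonzero(flat_valid)] = tok
        probability.ravel()[np.flatnonzero(flat_valid)] = proba[
            np.arange(len(winner)), winner
        ]
    return PredictionGrid(tokens=tokens, probability=probability)
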