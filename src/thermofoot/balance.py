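"""SMOTE class balancing and cross-validated SVM evaluation.

The screening datasets are case-heavy (e.g. 88 diabetic vs 34 healthy), so the
minority class is oversampled with SMOTE: each synthetic sample sits on the
segment between a minority sample and one of its k nearest minority-class
neighbors, x_new = x + u * (x_nn - x) with u ~ U(0, 1). The published workflow
balances the whole feature table before cross-validation; a leakage-safe
variant (SMOTE refit inside each training fold) is also provided, since
whole-table oversampling before CV lets synthetic copies of test subjects leak
into training and biases metrics optimistically.

Classification uses an RBF-kernel SVM, either with the standard
hyperparameters gamma = 0.1, C = 1 or with (gamma, C) picked by randomized
search over log-uniform ranges by mean CV accuracy. Metrics (accuracy,
precision, recall, F1; diabetic = positive class) are reported as mean +/- std
over stratified 5-fold CV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


def smote(
    X,
    y,
    k_neighbors: int = 5,
    random_state: int | np.random.Generator | None = None,
) -> tuple[np.ndarray | pd.DataFrame, np.ndarray]:
    """Oversample the minority class to the majority count by interpolation.

    Original rows are preserved verbatim; each synthetic minority sample is
    x + u * (x_nn - x) for a random minority sample x, one of its k nearest
    minority neighbors x_nn, and u ~ U(0, 1). Already-balanced input is
    returned unchanged.
    """
    rng = np.random.default_rng(random_state)
    is_frame = isinstance(X, pd.DataFrame)
    A = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE here supports exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return (X.copy() if is_frame else A.copy()), y.copy()
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class has {n_min} samples, not enough for k_neighbors="
            f"{k_neighbors}; reduce k"
        )

    Xmin = A[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xmin)
    _, neighbor_idx = nn.kneighbors(Xmin)  # column 0 is the point itself

    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    anchors = Xmin[base]
    partners = Xmin[neighbor_idx[base, pick]]
    synthetic = anchors + u[:, None] * (partners - anchors)

    X_out = np.vstack([A, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    if is_frame:
        synth_df = pd.DataFrame(synthetic, columns=X.columns)
        X_out = pd.concat([X.reset_index(drop=True), synth_df], ignore_index=True)
    return X_out, y_out


class SMOTE(BaseEstimator):
    """Estimator wrapper around :func:`smote` (fit_resample interface)."""

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        return smote(X, y, k_neighbors=self.k_neighbors, random_state=self.random_state)


@dataclass
class SvmConfig:
    """RBF-kernel SVM settings.

    ``standard`` mode pins gamma = 0.1, C = 1; ``optimized`` mode draws
    (gamma, C) log-uniformly from the search ranges and keeps the pair with the
    best mean CV accuracy. The default ranges bracket the optima reported for
    plantar-thermogram datasets (gamma of order 1e-3..1e-2, C of order 1..1e2).
    """

    kernel: str = "rbf"
    gamma: float = 0.1
    C: float = 1.0
    mode: str = "standard"
    search_iterations: int = 50
    gamma_range: tuple[float, float] = (1e-4, 1.0)
    C_range: tuple[float, float] = (1e-1, 1e2)
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.C <= 0:
            raise ValueError("gamma and C must be positive")
        if self.mode not in ("standard", "optimized"):
            raise ValueError("mode must be 'standard' or 'optimized'")


@dataclass
class EvaluationReport:
    """Mean +/- std of the four CV metrics for one (approach, feature set) run."""

    approach: str
    feature_subset: list[str]
    metrics: dict[str, tuple[float, float]]   # name -> (mean, std)
    fold_metrics: pd.DataFrame                # folds x metrics
    svm_config: SvmConfig
    smote_applied: bool = False

    def to_row(self) -> dict:
        row: dict = {"approach": self.approach, "n_features": len(self.feature_subset),
                     "svm_mode": self.svm_config.mode, "smote": self.smote_applied}
        for name, (m, s) in self.metrics.items():
            row[f"{name}_mean"] = m
            row[f"{name}_std"] = s
        return row


def _subset(X, feature_subset: list[str] | None):
    if feature_subset is None:
        return X
    if not feature_subset:
        raise ValueError("feature subset is empty")
    if isinstance(X, pd.DataFrame):
        missing = [f for f in feature_subset if f not in X.columns]
        if missing:
            raise KeyError(f"features missing from table: {missing}")
        return X.loc[:, feature_subset]
    return np.asarray(X)[:, feature_subset]


def _fold_metric_row(y_true, y_pred) -> dict[str, float]:
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, pos_label=1, zero_division=0),
        "recall": recall_score(y_true, y_pred, pos_label=1, zero_division=0),
        "f1": f1_score(y_true, y_pred, pos_label=1, zero_division=0),
    }


def fit_eval_svm(
    X,
    y,
    feature_subset: list[str] | None = None,
    config: SvmConfig | None = None,
    approach: str = "",
    smote_in_fold: bool = False,
    smote_k: int = 5,
) -> EvaluationReport:
    """Stratified 5-fold CV evaluation of an RBF SVM on a feature subset.

    Per fold: optional SMOTE on the training portion only (leakage-safe mode),
    z-scaling fit on the training portion, SVM fit, metrics on the untouched
    held-out fold. Diabetic (label 1) is the positive class.
    """
    config = config or SvmConfig()
    Xs = _subset(X, feature_subset)
    A = np.asarray(Xs, dtype=np.float64)
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)

    rows = []
    for fold, (tr, te) in enumerate(skf.split(A, y)):
        X_tr, y_tr = A[tr], y[tr]
        if smote_in_fold:
            X_tr, y_tr = smote(X_tr, y_tr, k_neighbors=smote_k,
                               random_state=config.seed * 1000 + fold)
        scaler = StandardScaler().fit(X_tr)
        clf = SVC(kernel=config.kernel, gamma=config.gamma, C=config.C)
        clf.fit(scaler.transform(X_tr), y_tr)
        pred = clf.predict(scaler.transform(A[te]))
        rows.append(_fold_metric_row(y[te], pred))

    fold_df = pd.DataFrame(rows)
    metrics = {c: (float(fold_df[c].mean()), float(fold_df[c].std(ddof=0)))
               for c in fold_df.columns}
    names = (feature_subset if feature_subset is not None
             else list(map(str, _feature_cols(X))))
    return EvaluationReport(approach=approach, feature_subset=list(names),
                            metrics=metrics, fold_metrics=fold_df,
                            svm_config=config, smote_applied=smote_in_fold)


def _feature_cols(X):
    if isinstance(X, pd.DataFrame):
        return list(X.columns)
    return list(range(np.asarray(X).shape[1]))


def randomized_search_svm(
    X,
    y,
    feature_subset: list[str] | None = None,
    config: SvmConfig | None = None,
) -> SvmConfig:
    """Randomized (gamma, C) search maximizing mean CV accuracy.

    Draws log-uniformly from the configured ranges; deterministic under the
    config seed. Returns a new config in 'optimized' mode with the best pair.
    """
    base = config or SvmConfig()
    rng = np.random.default_rng(base.seed)
    lo_g, hi_g = np.log(base.gamma_range[0]), np.log(base.gamma_range[1])
    lo_c, hi_c = np.log(base.C_range[0]), np.log(base.C_range[1])

    best_acc, best = -np.inf, None
    for _ in range(base.search_iterations):
        gamma = float(np.exp(rng.uniform(lo_g, hi_g)))
        C = float(np.exp(rng.uniform(lo_c, hi_c)))
        trial = SvmConfig(gamma=gamma, C=C, mode="optimized", n_folds=base.n_folds,
                          seed=base.seed, search_iterations=base.search_iterations,
                          gamma_range=base.gamma_range, C_range=base.C_range)
        rep = fit_eval_svm(X, y, feature_subset=feature_subset, config=trial)
        acc = rep.metrics["accuracy"][0]
        if acc > best_acc:
            best_acc, best = acc, trial
    return best


def smote_ablation(
    X,
    y,
    feature_subsets: dict[str, list[str]],
    config: SvmConfig | None = None,
    smote_k: int = 5,
) -> pd.DataFrame:
    """Paired SMOTE-on vs SMOTE-off evaluation with identical folds and seeds.

    SMOTE is applied inside each training fold (leakage-safe) in the 'on' arm.
    Returns one row per (approach, arm) plus per-metric deltas (on - off).
    """
    config = config or SvmConfig()
    rows = []
    for approach, subset in feature_subsets.items():
        off = fit_eval_svm(X, y, feature_subset=subset, config=config,
                           approach=approach, smote_in_fold=False)
        on = fit_eval_svm(X, y, feature_subset=subset, config=config,
                          approach=approach, smote_in_fold=True, smote_k=smote_k)
        for rep in (off, on):
            rows.append(rep.to_row())
        delta = {"approach": approach, "svm_mode": config.mode, "smote": "delta"}
        for m in ("accuracy", "precision", "recall", "f1"):
            delta[f"{m}_mean"] = on.metrics[m][0] - off.metrics[m][0]
        rows.append(delta)
    return pd.DataFrame(rows)


def format_report_table(reports: list[EvaluationReport]) -> str:
    """Plain-text metric table: rows = approach, columns = mean +/- std."""
    header = f"{'Approach':<24}{'Accuracy':<18}{'Precision':<18}{'Recall':<18}{'F1-Score':<18}"
    lines = [header, "-" * len(header)]
    for rep in reports:
        cells = [f"{rep.approach} ({rep.svm_config.mode})"[:23].ljust(24)]
        for m in ("accuracy", "precision", "recall", "f1"):
            mean, std = rep.metrics[m]
            cells.append(f"{mean:.4f} ± {std:.4f}".ljust(18))
        lines.append("".join(cells))
    return "\n".join(lines)
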