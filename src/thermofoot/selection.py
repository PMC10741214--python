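"""Feature pruning, ranking and cross-approach consensus.

The selection stage mirrors the published workflow: Pearson-correlation
pruning (|r| > 0.95 drops the later of each pair), then feature ranking by
four approaches — L1-penalized logistic regression (lasso), random-forest
impurity importance, and two dropout-based neural selectors (concrete input
gate and variational Gaussian dropout) — plus a univariate logistic/AUC-ROC
ranking. Each ranker scores features per fold of a stratified 5-fold split
(80:20 train/test) and averages the five fold scores into its final relevance.

All rankers are scikit-learn style estimators: ``fit(X, y)`` populates
``scores_`` (mean relevance per feature), ``fold_scores_`` (folds x features)
and ``ranking_`` / ``ranked_features_`` (descending relevance, ties broken by
column order). A min-rank consensus across approaches reproduces the
"features in coincidence" summary: a feature qualifies if every approach ranks
it inside the cutoff, and its final rank is the best (minimum) rank achieved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from ._nn import ConcreteGateNet, VariationalGateNet, train_gated_net

logger = logging.getLogger(__name__)


@dataclass
class SelectorConfig:
    """Training protocol shared by the ranking approaches.

    Neural-selector hyperparameters follow the published protocol: batch size
    32, 500 epochs, Adam with beta = (0.9, 0.999), learning rate 1e-2 for the
    concrete gate and 1e-3 for variational dropout, hidden dropout 0.5.
    """

    corr_threshold: float = 0.95
    n_folds: int = 5
    batch_size: int = 32
    epochs: int = 500
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    lr_concrete: float = 1e-2
    lr_variational: float = 1e-3
    hidden_dropout: float = 0.5
    concrete_temperature: float = 0.1
    top_k: int = 10
    consensus_cutoffs: tuple[int, ...] = (10, 20, 30, 50)
    rf_n_estimators: int = 500
    seed: int = 0


def _feature_names(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"x{i}" for i in range(np.asarray(X).shape[1])]


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Greedy Pearson-correlation pruning.

    Scans ordered column pairs (i < j); whenever |r_ij| exceeds the threshold
    the later column j is dropped. Constant columns have undefined r and are
    kept (logged). The survivors contain no pair above the threshold.
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X, y=None):
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        names = _feature_names(X)
        A = np.asarray(X, dtype=np.float64)
        if A.shape[0] < 2:
            raise ValueError("need at least 2 samples to estimate correlations")
        sd = A.std(axis=0)
        constant = sd == 0
        if constant.any():
            logger.info("constant features kept (undefined correlation): %s",
                        [names[i] for i in np.nonzero(constant)[0]])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(A, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)  # constant columns: uncorrelated

        d = A.shape[1]
        keep = np.ones(d, dtype=bool)
        for i in range(d):
            if not keep[i]:
                continue
            for j in range(i + 1, d):
                if keep[j] and abs(corr[i, j]) > self.threshold:
                    keep[j] = False
        self.support_ = keep
        self.selected_features_ = [n for n, k in zip(names, keep) if k]
        self.dropped_features_ = [n for n, k in zip(names, keep) if not k]
        self.n_features_in_ = d
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_features_]
        return np.asarray(X)[:, self.support_]


def _stable_ranking(scores: np.ndarray) -> np.ndarray:
    """Indices in descending score order; ties broken by column order."""
    return np.lexsort((np.arange(len(scores)), -scores))


class _CVRankerBase(BaseEstimator):
    """Stratified k-fold relevance scoring with per-fold averaging."""

    def __init__(self, n_folds: int = 5, random_state: int = 0):
        self.n_folds = n_folds
        self.random_state = random_state

    def _fold_scores(self, X_tr, y_tr, X_te, y_te, fold_seed: int) -> np.ndarray:
        raise NotImplementedError

    def fit(self, X, y):
        names = _feature_names(X)
        A = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) != 2:
            raise ValueError("ranking requires exactly two classes")
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.random_state)
        fold_scores = []
        for fold, (tr, te) in enumerate(skf.split(A, y)):
            s = self._fold_scores(A[tr], y[tr], A[te], y[te],
                                  fold_seed=self.random_state * 1000 + fold)
            fold_scores.append(np.asarray(s, dtype=np.float64))
        self.fold_scores_ = np.vstack(fold_scores)
        self.scores_ = self.fold_scores_.mean(axis=0)
        self.ranking_ = _stable_ranking(self.scores_)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.ranked_features_ = [names[i] for i in self.ranking_]
        return self

    def top_k(self, k: int = 10) -> list[str]:
        return self.ranked_features_[:k]


class UnivariateAUCRanker(_CVRankerBase):
    """Single-feature logistic regression scored by held-out AUC-ROC."""

    def _fold_scores(self, X_tr, y_tr, X_te, y_te, fold_seed):
        aucs = np.empty(X_tr.shape[1])
        for j in range(X_tr.shape[1]):
            col_tr, col_te = X_tr[:, [j]], X_te[:, [j]]
            if col_tr.std() == 0:
                aucs[j] = 0.5
                continue
            clf = LogisticRegression(max_iter=1000)
            clf.fit(col_tr, y_tr)
            aucs[j] = roc_auc_score(y_te, clf.decision_function(col_te))
        return aucs


class LassoRanker(_CVRankerBase):
    """L1-penalized logistic regression; relevance = |coefficient|.

    Features are z-scored on the training portion of each fold; the penalty
    strength is chosen by inner cross-validation.
    """

    def __init__(self, n_folds: int = 5, random_state: int = 0,
                 Cs: int = 10, inner_cv: int = 3):
        super().__init__(n_folds=n_folds, random_state=random_state)
        self.Cs = Cs
        self.inner_cv = inner_cv

    def _fold_scores(self, X_tr, y_tr, X_te, y_te, fold_seed):
        scaler = StandardScaler().fit(X_tr)
        clf = LogisticRegressionCV(
            Cs=self.Cs, cv=self.inner_cv, l1_ratios=(1.0,), solver="liblinear",
            scoring="accuracy", max_iter=2000, random_state=fold_seed,
            use_legacy_attributes=False,
        )
        clf.fit(scaler.transform(X_tr), y_tr)
        return np.abs(clf.coef_.ravel())


class RandomForestRanker(_CVRankerBase):
    """Random-forest impurity-decrease importances averaged over folds."""

    def __init__(self, n_folds: int = 5, random_state: int = 0, n_estimators: int = 500):
        super().__init__(n_folds=n_folds, random_state=random_state)
        self.n_estimators = n_estimators

    def _fold_scores(self, X_tr, y_tr, X_te, y_te, fold_seed):
        rf = RandomForestClassifier(n_estimators=self.n_estimators,
                                    random_state=fold_seed, n_jobs=1)
        rf.fit(X_tr, y_tr)
        return rf.feature_importances_


class _GatedNetRankerBase(_CVRankerBase):
    """Shared fold protocol of the two dropout-based neural rankers."""

    def __init__(self, n_folds: int = 5, random_state: int = 0, epochs: int = 500,
                 batch_size: int = 32, lr: float = 1e-2, hidden_dropout: float = 0.5,
                 adam_beta1: float = 0.9, adam_beta2: float = 0.999):
        super().__init__(n_folds=n_folds, random_state=random_state)
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.hidden_dropout = hidden_dropout
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2

    def _build_net(self, n_in: int, rng: np.random.Generator):
        raise NotImplementedError

    def _relevance(self, net) -> np.ndarray:
        raise NotImplementedError

    def _fold_scores(self, X_tr, y_tr, X_te, y_te, fold_seed):
        rng = np.random.default_rng(fold_seed)
        scaler = StandardScaler().fit(X_tr)
        Z = scaler.transform(X_tr)
        net = self._build_net(Z.shape[1], rng)
        try:
            train_gated_net(
                net, Z, y_tr, rng, lr=self.lr, epochs=self.epochs,
                batch_size=self.batch_size,
                beta1=self.adam_beta1, beta2=self.adam_beta2,
            )
        except FloatingPointError as err:
            raise FloatingPointError(f"fold seeded {fold_seed}: {err}") from err
        return self._relevance(net)


class ConcreteDropoutRanker(_GatedNetRankerBase):
    """Concrete-dropout input gate; relevance = learned keep-probability p_i."""

    def __init__(self, n_folds: int = 5, random_state: int = 0, epochs: int = 500,
                 batch_size: int = 32, lr: float = 1e-2, hidden_dropout: float = 0.5,
                 adam_beta1: float = 0.9, adam_beta2: float = 0.999,
                 temperature: float = 0.1, l0_weight: float | None = None):
        super().__init__(n_folds=n_folds, random_state=random_state, epochs=epochs,
                         batch_size=batch_size, lr=lr, hidden_dropout=hidden_dropout,
                         adam_beta1=adam_beta1, adam_beta2=adam_beta2)
        self.temperature = temperature
        self.l0_weight = l0_weight

    def _build_net(self, n_in, rng):
        return ConcreteGateNet(n_in, rng, temperature=self.temperature,
                               l0_weight=self.l0_weight,
                               hidden_dropout=self.hidden_dropout)

    def _relevance(self, net):
        return net.keep_prob


class VariationalDropoutRanker(_GatedNetRankerBase):
    """Variational Gaussian dropout; relevance = -log alpha_i (small noise = relevant)."""

    def __init__(self, n_folds: int = 5, random_state: int = 0, epochs: int = 500,
                 batch_size: int = 32, lr: float = 1e-3, hidden_dropout: float = 0.5,
                 adam_beta1: float = 0.9, adam_beta2: float = 0.999,
                 init_log_alpha: float = -1.0):
        super().__init__(n_folds=n_folds, random_state=random_state, epochs=epochs,
                         batch_size=batch_size, lr=lr, hidden_dropout=hidden_dropout,
                         adam_beta1=adam_beta1, adam_beta2=adam_beta2)
        self.init_log_alpha = init_log_alpha

    def _build_net(self, n_in, rng):
        return VariationalGateNet(n_in, rng, init_log_alpha=self.init_log_alpha,
                                  hidden_dropout=self.hidden_dropout)

    def _relevance(self, net):
        return -net.log_alpha


def make_rankers(config: SelectorConfig | None = None) -> dict[str, _CVRankerBase]:
    """The four published ranking approaches, configured per protocol."""
    c = config or SelectorConfig()
    common = dict(n_folds=c.n_folds, random_state=c.seed)
    return {
        "lasso": LassoRanker(**common),
        "random_forest": RandomForestRanker(**common, n_estimators=c.rf_n_estimators),
        "concrete_dropout": ConcreteDropoutRanker(
            **common, epochs=c.epochs, batch_size=c.batch_size, lr=c.lr_concrete,
            hidden_dropout=c.hidden_dropout, adam_beta1=c.adam_beta1,
            adam_beta2=c.adam_beta2, temperature=c.concrete_temperature,
        ),
        "variational_dropout": VariationalDropoutRanker(
            **common, epochs=c.epochs, batch_size=c.batch_size, lr=c.lr_variational,
            hidden_dropout=c.hidden_dropout, adam_beta1=c.adam_beta1,
            adam_beta2=c.adam_beta2,
        ),
    }


@dataclass
class ConsensusResult:
    """Min-rank consensus across ranking approaches.

    ``table`` has one row per qualifying feature: per-approach 1-based ranks,
    the final (minimum) rank and the cutoff bucket label ('<10', '<20', ...).
    """

    table: pd.DataFrame
    cutoffs: tuple[int, ...] = (10, 20, 30, 50)
    max_rank: int = 50


def consensus(
    rankings: dict[str, list[str]],
    cutoffs: tuple[int, ...] = (10, 20, 30, 50),
    max_rank: int = 50,
) -> ConsensusResult:
    """Features ranked inside ``max_rank`` by every approach; final rank = min.

    ``rankings`` maps approach name to its ordered feature list (best first).
    A feature qualifies only if all approaches rank it strictly below
    ``max_rank`` (1-based rank <= max_rank - 1 ... i.e. rank < max_rank). The
    bucket label is the smallest cutoff exceeding the final rank.
    """
    if len(rankings) < 2:
        raise ValueError("consensus needs at least two rankings")
    approaches = list(rankings)
    rank_maps = {a: {f: i + 1 for i, f in enumerate(lst)} for a, lst in rankings.items()}
    universe = set.intersection(*(set(lst) for lst in rankings.values()))

    rows = []
    for feat in universe:
        ranks = {a: rank_maps[a][feat] for a in approaches}
        if any(r >= max_rank for r in ranks.values()):
            continue
        final = min(ranks.values())
        bucket = next(f"<{c}" for c in sorted(cutoffs) if final < c)
        rows.append({"feature": feat, **{f"rank_{a}": ranks[a] for a in approaches},
                     "final_rank": final, "bucket": bucket})
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["final_rank", "feature"]).reset_index(drop=True)
    return ConsensusResult(table=table, cutoffs=cutoffs, max_rank=max_rank)


def format_consensus_report(result: ConsensusResult) -> str:
    """Plain-text consensus summary grouped by rank bucket."""
    lines = ["Features in coincidence across approaches", "=" * 44]
    if not len(result.table):
        lines.append("(none)")
        return "\n".join(lines)
    for c in sorted(result.cutoffs):
        sub = result.table[result.table["bucket"] == f"<{c}"]
        lines.append(f"Rank < {c}:")
        if len(sub):
            for _, row in sub.iterrows():
                lines.append(f"  {row['feature']} (final rank {row['final_rank']})")
        else:
            lines.append("  (none)")
    return "\n".join(lines)
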