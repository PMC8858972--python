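"""Iterative biomarker panel selection.

The selection loop combines three ingredients:

1. a similarity matrix of pairwise Hoeffding D statistics (a nonparametric
   rank measure of bivariate dependence, scaled to [-0.5, 1]) over the
   surviving features — the "variable clustering" view of redundancy;
2. random-forest feature importances under the three-group labels;
3. one elimination per iteration: the most dependent feature pair is found
   and its lower-importance member dropped, after which the reduced model's
   cross-validated accuracy is recorded.

The loop stops when accuracy consistently and markedly deteriorates
(configurable drop ``delta`` sustained for ``patience`` iterations) and
returns the best-scoring panel seen, preferring fewer features on ties.

Hoeffding's D here uses midranks and the standard half-weight convention
for ties in the bivariate rank counts::

    D = 30 * [ (n-2)(n-3) D1 + D2 - 2(n-2) D3 ] / [ n(n-1)(n-2)(n-3)(n-4) ]

with ``D1 = sum Q_i (Q_i - 1)``, ``D2 = sum (R_i-1)(R_i-2)(S_i-1)(S_i-2)``,
``D3 = sum (R_i-2)(S_i-2) Q_i``, where R, S are the midranks of x and y and
``Q_i`` counts points strictly below-left of point i, with weight 1/2 for
points tied in exactly one coordinate and 1/4 for points tied in both.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "hoeffding_d",
    "similarity_matrix",
    "most_correlated_pair",
    "rf_importance",
    "iterative_elimination",
    "RFConfig",
    "EliminationConfig",
    "EliminationStep",
    "SelectionTrace",
    "dependence_dendrogram",
]


def _bivariate_q(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Q_i: weighted count of points below-left of each point (ties get the
    half-weight convention; the self-pair is excluded)."""
    lx = np.less.outer(x, x)   # lx[j, i] = x_j < x_i
    ly = np.less.outer(y, y)
    ex = np.equal.outer(x, x)
    ey = np.equal.outer(y, y)
    w = (
        (lx & ly) * 1.0
        + (ex & ly) * 0.5
        + (lx & ey) * 0.5
        + (ex & ey) * 0.25
    )
    np.fill_diagonal(w, 0.0)
    return w.sum(axis=0)


def hoeffding_d(x, y) -> float:
    """Scaled Hoeffding D statistic of dependence between two samples.

    Symmetric in its arguments, invariant under strictly increasing
    transforms of either variable, and 1.0 exactly for any monotone
    tie-free relationship.  Requires n >= 5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 5:
        raise ValueError("Hoeffding's D requires at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variable (all ties)")
    r = rankdata(x)  # midranks
    s = rankdata(y)
    q = _bivariate_q(x, y)
    d1 = float(np.sum(q * (q - 1)))
    d2 = float(np.sum((r - 1) * (r - 2) * (s - 1) * (s - 2)))
    d3 = float(np.sum((r - 2) * (s - 2) * q))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom


def similarity_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of pairwise scaled Hoeffding D; diagonal 1 by
    convention.  Degenerate (constant) features are excluded with a
    warning."""
    if len(X) < 5:
        raise ValueError("need at least 5 samples")
    usable = []
    for col in X.columns:
        if np.ptp(X[col].to_numpy(dtype=float)) == 0:
            logger.warning("excluding degenerate feature %s from similarity", col)
        else:
            usable.append(col)
    if len(usable) < 2:
        raise ValueError("need at least 2 non-degenerate features")
    mat = pd.DataFrame(np.eye(len(usable)), index=usable, columns=usable)
    arrays = {c: X[c].to_numpy(dtype=float) for c in usable}
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            d = hoeffding_d(arrays[a], arrays[b])
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def most_correlated_pair(sim: pd.DataFrame) -> tuple[str, str]:
    """The off-diagonal argmax of the similarity matrix; exact ties broken
    by lexicographic feature label for determinism."""
    if sim.shape[0] < 2:
        raise ValueError("need at least 2 features")
    best: tuple[str, str] | None = None
    best_val = -np.inf
    cols = list(sim.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = tuple(sorted((a, b)))
            val = float(sim.loc[a, b])
            if val > best_val or (val == best_val and (best is None or pair < best)):
                best_val = val
                best = pair
    assert best is not None
    return best


def dependence_dendrogram(sim: pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical clustering on the 1 - D dissimilarity
    (reporting only; elimination uses just the top pair)."""
    dist = 1.0 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    return average(squareform(dist, checks=False))


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings shared by importance ranking and CV models."""

    n_estimators: int = 500
    max_features: str | float = "sqrt"
    importance: str = "impurity"  # or "permutation"
    seed: int = 0

    def classifier(self, seed_offset: int = 0) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=(self.seed + seed_offset) % (2**31),
            n_jobs=1,
        )


def rf_importance(X: pd.DataFrame, y, cfg: RFConfig | None = None) -> pd.Series:
    """Nonnegative per-feature importance from a seeded random forest.

    ``impurity`` (default) uses mean decrease of Gini impurity;
    ``permutation`` uses out-of-sample permutation importance averaged over
    5 shuffles (slower, less biased toward high-cardinality features).
    """
    cfg = cfg or RFConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain at least two classes")
    clf = cfg.classifier().fit(X, y)
    if cfg.importance == "impurity":
        imp = clf.feature_importances_
    elif cfg.importance == "permutation":
        result = permutation_importance(
            clf, X, y, n_repeats=5, random_state=cfg.seed, n_jobs=1
        )
        imp = np.clip(result.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown importance kind {cfg.importance!r}")
    return pd.Series(imp, index=X.columns, name="importance")


def _cv_accuracy(X: pd.DataFrame, y: np.ndarray, cfg: "EliminationConfig") -> float:
    """Mean repeated stratified 3-fold accuracy (percent) of the current
    feature set — the stopping-rule score."""
    rkf = RepeatedStratifiedKFold(
        n_splits=3, n_repeats=cfg.stop_cv_reps, random_state=cfg.seed % (2**31)
    )
    correct = total = 0
    for rep, (tr, te) in enumerate(rkf.split(X, y)):
        clf = cfg.rf.classifier(seed_offset=1000 + rep)
        clf.fit(X.iloc[tr], y[tr])
        correct += int((clf.predict(X.iloc[te]) == y[te]).sum())
        total += len(te)
    return 100.0 * correct / total


@dataclass
class EliminationConfig:
    """Knobs of the iterative elimination loop."""

    rf: RFConfig = field(default_factory=RFConfig)
    delta: float = 2.0       # accuracy drop (percentage points) deemed "dramatic"
    patience: int = 2        # consecutive deteriorated iterations before stopping
    min_features: int = 5
    stop_cv_reps: int = 5    # repeats of stratified 3-fold for the stopping score
    seed: int = 0


@dataclass(frozen=True)
class EliminationStep:
    iteration: int
    eliminated: str
    eliminated_importance: float
    partner: str
    partner_importance: float
    pair_similarity: float
    cv_accuracy: float
    n_features_after: int

    def __post_init__(self) -> None:
        if self.eliminated_importance > self.partner_importance:
            raise ValueError("eliminated feature must not outrank its partner")


@dataclass
class SelectionTrace:
    """Full record of an elimination run: per-iteration steps plus the
    retained panel (the best-scoring feature set, smallest on ties)."""

    initial_features: list[str]
    initial_accuracy: float
    steps: list[EliminationStep]
    retained: list[str]
    best_accuracy: float
    stopped_early: bool

    def eliminated_order(self) -> list[str]:
        return [s.eliminated for s in self.steps]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "initial_features": self.initial_features,
            "initial_accuracy": self.initial_accuracy,
            "steps": [asdict(s) for s in self.steps],
            "retained": self.retained,
            "best_accuracy": self.best_accuracy,
            "stopped_early": self.stopped_early,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionTrace":
        doc = json.loads(Path(path).read_text())
        doc["steps"] = [EliminationStep(**s) for s in doc["steps"]]
        return cls(**doc)


def iterative_elimination(
    X: pd.DataFrame,
    y,
    cfg: EliminationConfig | None = None,
) -> SelectionTrace:
    """Run the full elimination loop on a screened feature matrix.

    Per iteration: recompute the Hoeffding-D similarity matrix over the
    surviving features, locate the most dependent pair, rank both members by
    random-forest importance, drop the weaker one, and score the reduced
    panel by repeated 3-fold CV accuracy.  Stops after ``patience``
    consecutive iterations more than ``delta`` accuracy points below the
    best score, or at ``min_features``; returns the best panel seen.
    """
    cfg = cfg or EliminationConfig()
    y = np.asarray(y)
    features = list(X.columns)
    if len(features) < 2:
        raise ValueError("need at least 2 features to eliminate from")

    acc0 = _cv_accuracy(X, y, cfg)
    history: list[tuple[float, list[str]]] = [(acc0, list(features))]
    steps: list[EliminationStep] = []
    best_acc = acc0
    bad_streak = 0
    stopped_early = False

    it = 0
    while len(features) > cfg.min_features:
        it += 1
        sub = X[features]
        sim = similarity_matrix(sub)
        a, b = most_correlated_pair(sim)
        imp = rf_importance(sub, y, cfg.rf)
        # drop the lower-importance member; exact tie -> drop the
        # lexicographically later label (deterministic)
        if imp[a] < imp[b] or (imp[a] == imp[b] and a > b):
            drop, keep = a, b
        else:
            drop, keep = b, a
        features = [f for f in features if f != drop]
        acc = _cv_accuracy(X[features], y, cfg)
        steps.append(
            EliminationStep(
                iteration=it,
                eliminated=drop,
                eliminated_importance=float(imp[drop]),
                partner=keep,
                partner_importance=float(imp[keep]),
                pair_similarity=float(sim.loc[a, b]),
                cv_accuracy=acc,
                n_features_after=len(features),
            )
        )
        history.append((acc, list(features)))
        logger.debug(
            "iteration %d: dropped %s (imp %.4f) paired with %s (imp %.4f, D %.3f); "
            "accuracy %.1f%%",
            it, drop, imp[drop], imp[keep], imp[keep], acc,
        )
        best_acc = max(best_acc, acc)
        if acc < best_acc - cfg.delta:
            bad_streak += 1
            if bad_streak >= cfg.patience:
                stopped_early = True
                break
        else:
            bad_streak = 0

    # best accuracy wins; ties go to the smallest panel (scanning in
    # elimination order, later entries have fewer features)
    best_acc_final, retained = history[0]
    for acc, feats in history[1:]:
        if acc >= best_acc_final:
            best_acc_final, retained = acc, feats
    return SelectionTrace(
        initial_features=list(X.columns),
        initial_accuracy=acc0,
        steps=steps,
        retained=retained,
        best_accuracy=best_acc_final,
        stopped_early=stopped_early,
    )
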