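"""Cross-validated evaluation of a glycan panel's discriminating ability.

Pairwise group comparisons (no fibrosis vs early-moderate, early-moderate vs
advanced, no fibrosis vs advanced; optionally a METAVIR-stage regrouping)
are each scored by a seeded random forest under four cross-validation
schemes:

* ``apparent`` — train and score on all samples (optimistic by design),
* ``loocv`` — leave-one-out: one held-out score per sample,
* ``subsample3fold`` — repeated random stratified 2:1 train/test splits,
* ``repeated3fold`` — repeated full stratified 3-fold partitions,

the repeated schemes defaulting to 200 repetitions.  Discrimination is
summarized by the ROC AUC (Mann-Whitney form) with a DeLong 95% confidence
interval, plus accuracy, sensitivity, specificity, PPV and NPV at the
operating point that maximizes sensitivity subject to specificity >= 90%
(no ROC interpolation; thresholds are the observed scores).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import (
    LeaveOneOut,
    RepeatedStratifiedKFold,
    StratifiedShuffleSplit,
)

from .cohort import CohortTable
from .select import RFConfig

logger = logging.getLogger(__name__)

__all__ = [
    "cv_scores",
    "auc_ci",
    "auc_ci_bootstrap",
    "sens_at_spec",
    "operating_point_metrics",
    "evaluate_groupings",
    "EvalConfig",
    "EvalReport",
    "SCHEMES",
]

SCHEMES = ("apparent", "loocv", "subsample3fold", "repeated3fold")

COMPARISONS = {
    "g1_vs_g2": (1, 2),
    "g2_vs_g3": (2, 3),
    "g1_vs_g3": (1, 3),
}

#: Alternative METAVIR regrouping: no-to-early (healthy, 0, 1) vs moderate
#: to significant (2, 3), and moderate-significant (2, 3) vs cirrhosis (4).
STAGE_COMPARISONS = {
    "stage01_vs_stage23": (("healthy", "0", "1"), ("2", "3")),
    "stage23_vs_stage4": (("2", "3"), ("4",)),
}


def _check_binary(y: np.ndarray) -> None:
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")


def cv_scores(
    X: pd.DataFrame,
    y,
    model_cfg: RFConfig | None = None,
    scheme: str = "loocv",
    reps: int = 200,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Out-of-fold class-1 probability scores under one CV scheme.

    Returns a list of ``(scores, labels)`` pairs: a single pair for
    ``apparent`` and ``loocv``, one pair per repetition for the repeated
    schemes.  Folds are stratified, so every training fold sees both
    classes.  Deterministic given the seed.
    """
    model_cfg = model_cfg or RFConfig()
    y = np.asarray(y)
    _check_binary(y)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    X = X.reset_index(drop=True)

    def fit_score(tr: np.ndarray, te: np.ndarray, offset: int) -> np.ndarray:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("training fold with a single class despite stratification")
        clf = model_cfg.classifier(seed_offset=offset)
        clf.fit(X.iloc[tr], y[tr])
        pos = list(clf.classes_).index(1)
        return clf.predict_proba(X.iloc[te])[:, pos]

    if scheme == "apparent":
        idx = np.arange(len(y))
        return [(fit_score(idx, idx, 0), y.copy())]
    if scheme == "loocv":
        scores = np.empty(len(y))
        for i, (tr, te) in enumerate(LeaveOneOut().split(X)):
            scores[te] = fit_score(tr, te, i)
        return [(scores, y.copy())]
    if scheme == "subsample3fold":
        if min(np.bincount(y)) < 3:
            raise ValueError("each class needs >= 3 samples for 2:1 stratified splits")
        splitter = StratifiedShuffleSplit(
            n_splits=reps, test_size=1 / 3, random_state=seed % (2**31)
        )
        return [
            (fit_score(tr, te, r), y[te].copy())
            for r, (tr, te) in enumerate(splitter.split(X, y))
        ]
    if scheme == "repeated3fold":
        if min(np.bincount(y)) < 3:
            raise ValueError("each class needs >= 3 samples for stratified 3-fold")
        rkf = RepeatedStratifiedKFold(
            n_splits=3, n_repeats=reps, random_state=seed % (2**31)
        )
        out = []
        oof = np.empty(len(y))
        for k, (tr, te) in enumerate(rkf.split(X, y)):
            oof[te] = fit_score(tr, te, k)
            if k % 3 == 2:  # one full partition assembled
                out.append((oof.copy(), y.copy()))
                oof = np.empty(len(y))
        return out
    raise ValueError(f"unknown CV scheme {scheme!r}; expected one of {SCHEMES}")


# -- ROC machinery ----------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """ROC AUC (Mann-Whitney statistic) with a DeLong confidence interval.

    The variance is estimated from the per-sample placement structure
    (DeLong's components); the interval is normal-theory and clipped to
    [0, 1].  Degenerate zero-variance cases (e.g. perfect separation)
    collapse the interval onto the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_binary(labels)
    pos = scores[labels == np.max(labels)]
    neg = scores[labels == np.min(labels)]
    m, n = len(pos), len(neg)
    allx = np.concatenate([pos, neg])
    tx = _midrank(allx)
    tpos = _midrank(pos)
    tneg = _midrank(neg)
    auc = (tx[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tx[:m] - tpos) / n            # placements of positives
    v01 = 1.0 - (tx[m:] - tneg) / m      # placements of negatives
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = norm.ppf(0.5 + level / 2)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    return float(auc), min(lo, float(auc)), max(hi, float(auc))


def auc_ci_bootstrap(
    scores, labels, level: float = 0.95, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile-bootstrap alternative to the DeLong interval (stratified
    resampling within each class)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    auc, _, _ = auc_ci(scores, labels, level)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == np.max(labels))
    neg_idx = np.flatnonzero(labels == np.min(labels))
    stats = []
    for _ in range(n_boot):
        bi = np.concatenate(
            [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        )
        stats.append(auc_ci(scores[bi], labels[bi])[0])
    lo, hi = np.quantile(stats, [(1 - level) / 2, 0.5 + level / 2])
    return float(auc), float(min(lo, auc)), float(max(hi, auc))


def _confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float):
    pred = scores >= threshold
    pos = labels == np.max(labels)
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fp, fn, tn


def sens_at_spec(scores, labels, target_spec: float = 0.90) -> float:
    """Maximum sensitivity among observed-score thresholds achieving
    specificity >= ``target_spec`` (no interpolation).  Returns 0 with a
    warning when no threshold qualifies."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_binary(labels)
    best = None
    for t in np.unique(scores):
        tp, fp, fn, tn = _confusion_at(scores, labels, t)
        spec = tn / (tn + fp)
        if spec >= target_spec:
            sens = tp / (tp + fn)
            best = sens if best is None else max(best, sens)
    if best is None:
        warnings.warn(
            f"no threshold reaches specificity {target_spec:.0%}; reporting 0",
            stacklevel=2,
        )
        return 0.0
    return float(best)


def operating_point_metrics(
    scores,
    labels,
    target_spec: float = 0.90,
    prevalence: float | None = None,
) -> dict[str, float]:
    """Accuracy/sensitivity/specificity/PPV/NPV at the fixed-specificity
    operating point.

    The threshold maximizes sensitivity subject to specificity >=
    ``target_spec`` (highest qualifying threshold on ties).  PPV/NPV use the
    observed class prevalence unless an external ``prevalence`` override is
    given.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_binary(labels)
    best = None
    for t in np.unique(scores)[::-1]:
        tp, fp, fn, tn = _confusion_at(scores, labels, t)
        spec = tn / (tn + fp)
        if spec >= target_spec:
            sens = tp / (tp + fn)
            if best is None or sens > best[0]:
                best = (sens, spec, tp, fp, fn, tn)
    if best is None:
        warnings.warn(
            f"no threshold reaches specificity {target_spec:.0%}", stacklevel=2
        )
        nanrow = {k: float("nan") for k in ("accuracy", "ppv", "npv")}
        return {"sensitivity": 0.0, "specificity": 1.0, **nanrow}
    sens, spec, tp, fp, fn, tn = best
    if prevalence is None:
        ppv = tp / (tp + fp) if tp + fp else float("nan")
        npv = tn / (tn + fn) if tn + fn else float("nan")
    else:
        p = prevalence
        ppv = sens * p / (sens * p + (1 - spec) * (1 - p))
        npv = spec * (1 - p) / (spec * (1 - p) + (1 - sens) * p)
    return {
        "sensitivity": float(sens),
        "specificity": float(spec),
        "accuracy": float((tp + tn) / (tp + fp + fn + tn)),
        "ppv": float(ppv),
        "npv": float(npv),
    }


@dataclass
class EvalConfig:
    rf: RFConfig = field(default_factory=RFConfig)
    schemes: tuple[str, ...] = SCHEMES
    reps: int = 200
    target_spec: float = 0.90
    ci_method: str = "delong"  # or "bootstrap"
    prevalence: float | None = None
    include_stage_regrouping: bool = False
    seed: int = 0


@dataclass
class EvalReport:
    """Per-comparison evaluation across CV schemes.

    ``metrics[scheme]`` holds AUC, its 95% CI, accuracy, sensitivity,
    specificity, PPV, NPV and sensitivity-at-target-specificity; repeated
    schemes add across-repetition SDs (``*_sd``).  Score vectors from the
    single-pass schemes are retained for ROC plotting.
    """

    comparison: str
    n_per_class: dict[str, int]
    metrics: dict[str, dict[str, float]]
    scores: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scheme, m in self.metrics.items():
            if not (0.0 <= m["auc"] <= 1.0):
                raise ValueError(f"{self.comparison}/{scheme}: AUC outside [0, 1]")
            if not (m["auc_ci_low"] <= m["auc"] <= m["auc_ci_high"]):
                raise ValueError(f"{self.comparison}/{scheme}: CI does not bracket AUC")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics).T.rename_axis("scheme")


def _interval_metrics(
    score_sets: list[tuple[np.ndarray, np.ndarray]],
    cfg: EvalConfig,
) -> dict[str, float]:
    """Metrics for one scheme; repeated schemes are summarized as the mean
    across repetitions with SDs."""
    per_rep = []
    for scores, labels in score_sets:
        if cfg.ci_method == "bootstrap":
            auc, lo, hi = auc_ci_bootstrap(scores, labels, seed=cfg.seed)
        else:
            auc, lo, hi = auc_ci(scores, labels)
        op = operating_point_metrics(
            scores, labels, cfg.target_spec, prevalence=cfg.prevalence
        )
        per_rep.append(
            {
                "auc": auc,
                "auc_ci_low": lo,
                "auc_ci_high": hi,
                "sens_at_target_spec": sens_at_spec(scores, labels, cfg.target_spec),
                **op,
            }
        )
    frame = pd.DataFrame(per_rep)
    out = frame.mean().to_dict()
    if len(per_rep) > 1:
        for col in ("auc", "accuracy", "sensitivity", "specificity"):
            out[f"{col}_sd"] = float(frame[col].std(ddof=1))
    # a mean of per-rep CIs can fail to bracket the mean AUC only by
    # floating pathology; clamp defensively
    out["auc_ci_low"] = min(out["auc_ci_low"], out["auc"])
    out["auc_ci_high"] = max(out["auc_ci_high"], out["auc"])
    return out


def evaluate_groupings(
    cohort: CohortTable,
    panel_features: list[str],
    cfg: EvalConfig | None = None,
) -> list[EvalReport]:
    """Evaluate a retained glycan panel on every pairwise group comparison.

    Each comparison trains fresh binary random forests on the panel columns
    and reports all configured CV schemes.  With
    ``cfg.include_stage_regrouping`` the METAVIR regrouping comparisons are
    appended when per-sample stages are available.
    """
    cfg = cfg or EvalConfig()
    missing = set(panel_features) - set(cohort.feature_columns)
    if missing:
        raise ValueError(f"panel features absent from cohort: {sorted(missing)}")

    tasks: list[tuple[str, pd.DataFrame, np.ndarray]] = []
    for name, (ga, gb) in COMPARISONS.items():
        X, y = cohort.binary_subset(ga, gb)
        tasks.append((name, X[panel_features], y))
    if cfg.include_stage_regrouping:
        stage = cohort.data["stage"].astype(str)
        if stage.isna().any() or (stage == "<NA>").any():
            logger.warning("METAVIR stages unavailable; skipping stage regrouping")
        else:
            for name, (neg, pos) in STAGE_COMPARISONS.items():
                mask = stage.isin(neg + pos)
                X = cohort.features.loc[mask, panel_features]
                y = stage[mask].isin(pos).to_numpy(dtype=int)
                tasks.append((name, X, y))

    reports = []
    for name, X, y in tasks:
        metrics: dict[str, dict[str, float]] = {}
        kept_scores: dict[str, list] = {}
        for scheme in cfg.schemes:
            sets = cv_scores(
                X, y, cfg.rf, scheme=scheme, reps=cfg.reps, seed=cfg.seed
            )
            metrics[scheme] = _interval_metrics(sets, cfg)
            if scheme in ("apparent", "loocv"):
                kept_scores[scheme] = sets[0][0].tolist()
        reports.append(
            EvalReport(
                comparison=name,
                n_per_class={"neg": int((y == 0).sum()), "pos": int((y == 1).sum())},
                metrics=metrics,
                scores=kept_scores,
            )
        )
    return reports
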