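"""Univariate screening of glycan features across the three fibrosis groups.

Each feature is tested by one-way ANOVA over the three groups; features with
no evidence of any group difference (p > alpha on the F-test) are discarded
before model development.  Post-hoc tests on the two adjacent-group
contrasts (group 1 vs 2, group 2 vs 3) classify when along fibrosis
progression a significant feature changes: ``early`` (only the first
transition), ``late`` (only the second) or ``both``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "anova_f",
    "filter_features",
    "classify_timing",
    "results_to_frame",
]

GROUPS = (1, 2, 3)


@dataclass(frozen=True)
class AnovaResult:
    """One feature's screening result."""

    feature: str
    f_stat: float
    p_value: float
    group_means: dict[int, float]
    p_12: float  # post-hoc p, group 1 vs 2
    p_23: float  # post-hoc p, group 2 vs 3

    def __post_init__(self) -> None:
        if self.f_stat < 0:
            raise ValueError("F statistic must be nonnegative")
        for p in (self.p_value, self.p_12, self.p_23):
            if not (0.0 <= p <= 1.0 or np.isnan(p)):
                raise ValueError("p values must lie in [0, 1]")


def _split_by_group(values: np.ndarray, groups: np.ndarray) -> list[np.ndarray]:
    samples = [values[groups == g] for g in GROUPS]
    for g, s in zip(GROUPS, samples):
        if len(s) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    return samples

def anova_f(
    values,
    groups,
    feature: str = "",
    posthoc: str = "tukey",
) -> AnovaResult:
    """Classical one-way ANOVA of one feature over the three groups.

    The F statistic follows the F(k-1, N-k) reference distribution.
    ``posthoc`` selects the pairwise follow-up test on adjacent groups:
    ``"tukey"`` (Tukey's HSD, the default), ``"welch-bonferroni"``
    (pairwise Welch t-tests with Bonferroni correction over the two
    contrasts), or ``"none"`` to skip the follow-up (timing classification
    then unavailable).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = _split_by_group(values, groups)
    if np.ptp(values) == 0:
        raise ValueError(f"degenerate feature {feature!r}: all values identical")
    means = {g: float(np.mean(s)) for g, s in zip(GROUPS, samples)}
    if all(np.ptp(s) == 0 for s in samples) and len(set(means.values())) > 1:
        # zero within-group variance with distinct means: F undefined (inf)
        raise ValueError(f"degenerate feature {feature!r}: zero within-group variance")
    f_stat, p_value = stats.f_oneway(*samples)
    if np.isnan(f_stat):  # identical group means with zero residual spread
        f_stat, p_value = 0.0, 1.0
    if posthoc == "none":
        p_12 = p_23 = float("nan")
    elif posthoc == "tukey":
        hsd = stats.tukey_hsd(*samples)
        p_12 = float(hsd.pvalue[0, 1])
        p_23 = float(hsd.pvalue[1, 2])
    elif posthoc == "welch-bonferroni":
        p_12 = min(1.0, 2 * stats.ttest_ind(samples[0], samples[1], equal_var=False).pvalue)
        p_23 = min(1.0, 2 * stats.ttest_ind(samples[1], samples[2], equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown posthoc test {posthoc!r}")
    return AnovaResult(
        feature=feature,
        f_stat=float(max(f_stat, 0.0)),
        p_value=float(np.clip(p_value, 0.0, 1.0)),
        group_means=means,
        p_12=p_12,
        p_23=p_23,
    )


def filter_features(
    table: CohortTable,
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> tuple[list[str], list[AnovaResult]]:
    """Screen every feature; keep those with ANOVA p <= alpha.

    Degenerate (constant) features are dropped with a warning rather than
    failing the whole screen.  Raises if nothing survives — on synthetic
    data that indicates effect sizes too small to study.
    """
    groups = table.groups.to_numpy()
    results: list[AnovaResult] = []
    retained: list[str] = []
    for feature in table.feature_columns:
        values = table.data[feature].to_numpy(dtype=float)
        try:
            res = anova_f(values, groups, feature=feature, posthoc=posthoc)
        except ValueError as exc:
            logger.warning("skipping feature %s: %s", feature, exc)
            continue
        results.append(res)
        if res.p_value <= alpha:
            retained.append(feature)
    if not retained:
        raise ValueError(
            "no features pass the ANOVA screen; check the data or (for "
            "synthetic cohorts) increase planted effect sizes"
        )
    return retained, results


def classify_timing(result: AnovaResult, alpha: float = 0.05) -> str:
    """Timing class of a screened feature from its adjacent-group post-hocs:
    ``early`` / ``late`` / ``both`` / ``indeterminate``."""
    early = result.p_12 <= alpha
    late = result.p_23 <= alpha
    if early and late:
        return "both"
    if early:
        return "early"
    if late:
        return "late"
    logger.info(
        "feature %s significant overall but in neither adjacent contrast",
        result.feature,
    )
    return "indeterminate"


def results_to_frame(results: list[AnovaResult], alpha: float = 0.05) -> pd.DataFrame:
    """Tabular screening report with per-group means and timing classes."""
    rows = []
    for r in results:
        rows.append(
            {
                "feature": r.feature,
                "F": r.f_stat,
                "p_value": r.p_value,
                "mean_g1": r.group_means[1],
                "mean_g2": r.group_means[2],
                "mean_g3": r.group_means[3],
                "p_g1_vs_g2": r.p_12,
                "p_g2_vs_g3": r.p_23,
                "retained": r.p_value <= alpha,
                "timing": classify_timing(r, alpha) if r.p_value <= alpha else "",
            }
        )
    return pd.DataFrame(rows).set_index("feature")
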