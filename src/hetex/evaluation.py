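"""Cohort-level discrimination analysis.

Each heterogeneity index is evaluated independently as a binary-outcome
discriminator: an empirical ROC curve with the tie-corrected Mann-Whitney
AUC, the Youden-optimal sensitivity/specificity pair, and a Kruskal-Wallis
test. AUCs are oriented so the reported value is >= 0.5, with the sign of
the orientation recorded; no multiple-testing correction is applied by
default (a Benjamini-Hochberg column is available opt-in).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RocResult", "roc_analysis", "kruskal_wallis", "evaluate_cohort"]


@dataclasses.dataclass
class RocResult:
    """Oriented ROC summary: auc >= 0.5; orientation is +1 when larger
    scores indicate the positive class and -1 when smaller scores do."""

    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    orientation: int


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Unoriented AUC via the tie-corrected (midrank) Mann-Whitney formula:
    tied score pairs across classes receive half credit."""
    ranks = stats.rankdata(scores)  # midranks
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u = float(ranks[labels == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n0 * n1)


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC over all thresholds for one index.

    The optimal operating point maximizes Youden's J = sensitivity +
    specificity - 1, ties broken in favor of higher sensitivity. The
    decision rule at the reported threshold is ``orientation * score >=
    orientation * threshold``.

    Raises
    ------
    ValueError
        If only one class is present or lengths differ.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0 or n0 + n1 != len(labels):
        raise ValueError("labels must contain both classes (0 and 1)")

    auc = mann_whitney_auc(scores, labels)
    orientation = 1 if auc >= 0.5 else -1
    if orientation == -1:
        auc = 1.0 - auc

    oriented = orientation * scores
    best = (-np.inf, -np.inf, np.nan, np.nan)  # (J, sens, spec, threshold)
    for thr in np.unique(oriented):
        pred = oriented >= thr
        sens = float((pred & (labels == 1)).sum()) / n1
        spec = float((~pred & (labels == 0)).sum()) / n0
        j = sens + spec - 1.0
        if (j, sens) > (best[0], best[1]):
            best = (j, sens, spec, thr)
    _, sens, spec, thr = best
    return RocResult(auc, sens, spec, float(orientation * thr), orientation)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square with k-1 df.

    All-identical data degenerates to H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def evaluate_cohort(table: pd.DataFrame, reference: str = "STAT_suv_mean",
                    bh_column: bool = False) -> pd.DataFrame:
    """Per-index ROC and Kruskal-Wallis report for a labeled cohort.

    Parameters
    ----------
    table : DataFrame
        One row per subject; an ``outcome`` column in {0, 1} plus one column
        per index (an optional ``subject_id`` column is ignored).
    reference : str
        The index every other index is compared against (the mean intratumor
        SUV by default); must be present.
    bh_column : bool
        Add a Benjamini-Hochberg adjusted p-value column (off by default, as
        the per-index tests are reported uncorrected).

    Returns
    -------
    DataFrame
        Sorted by AUC descending; columns feature, auc, sensitivity,
        specificity, threshold, orientation, kw_h, kw_p. ``.attrs`` carries
        ``n_better_auc`` and ``n_lower_p``: how many indices beat the
        reference AUC / p-value.
    """
    if "outcome" not in table.columns:
        raise ValueError("table must have an 'outcome' column")
    labels = table["outcome"].to_numpy(dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("outcome must contain both classes 0 and 1")
    feature_cols = [c for c in table.columns
                    if c not in ("outcome", "subject_id")]
    if reference not in feature_cols:
        raise ValueError(f"missing {reference} column")

    rows = []
    for name in feature_cols:
        scores = table[name].to_numpy(dtype=float)
        roc = roc_analysis(scores, labels)
        h, p = kruskal_wallis([scores[labels == 0], scores[labels == 1]])
        rows.append({"feature": name, "auc": roc.auc,
                     "sensitivity": roc.sensitivity,
                     "specificity": roc.specificity,
                     "threshold": roc.threshold,
                     "orientation": roc.orientation,
                     "kw_h": h, "kw_p": p})
    report = pd.DataFrame(rows)
    if bh_column:
        report["kw_p_bh"] = _benjamini_hochberg(report["kw_p"].to_numpy())
    ref = report.loc[report["feature"] == reference].iloc[0]
    report = report.sort_values("auc", ascending=False, kind="mergesort",
                                ignore_index=True)
    report.attrs["reference"] = reference
    report.attrs["n_better_auc"] = int(
        (report.loc[report["feature"] != reference, "auc"] > ref["auc"]).sum())
    report.attrs["n_lower_p"] = int(
        (report.loc[report["feature"] != reference, "kw_p"] < ref["kw_p"]).sum())
    return report


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj
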