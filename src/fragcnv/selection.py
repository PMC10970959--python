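"""Batch-wise correlation filtering of region features, plus a per-region
differential test.

High-dimensional binned fragment counts are heavily redundant: neighbouring
windows track the same copy-number and coverage structure. Before fitting a
classifier, features are partitioned into consecutive batches (genomic
order) and, within each batch, any feature whose mean absolute Pearson
correlation with the other batch members exceeds a threshold is dropped in
one simultaneous pass. Selection must run on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError


@dataclass
class SelectionResult:
    kept_feature_ids: list[str]
    removed_feature_ids: list[str]
    mean_abs_corr: pd.Series
    batch_size: int
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature_id": self.mean_abs_corr.index,
                "mean_abs_r": self.mean_abs_corr.to_numpy(),
            }
        )
        kept = set(self.kept_feature_ids)
        df["kept"] = [f in kept for f in df["feature_id"]]
        return df


def _batch_mean_abs_corr(block: np.ndarray) -> np.ndarray:
    """Mean |Pearson r| of each column with the other columns of the block.

    Zero-variance (constant) columns get mean |r| = 0, and their
    correlations with other columns count as 0.
    """
    n_feat = block.shape[1]
    if n_feat == 1:
        return np.zeros(1)
    sd = block.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(block, rowvar=False)
    r = np.abs(np.nan_to_num(r, nan=0.0))
    np.fill_diagonal(r, 0.0)
    mean_abs = r.sum(axis=1) / (n_feat - 1)
    mean_abs[constant] = 0.0
    return mean_abs


def correlation_filter(
    train_matrix: pd.DataFrame, batch_size: int = 1000, threshold: float = 0.7
) -> SelectionResult:
    """Drop features whose within-batch mean |r| exceeds ``threshold``.

    Features are taken in column (genomic) order in consecutive batches of
    ``batch_size`` (last batch smaller); correlations are computed across
    the training samples; removal is a single simultaneous pass — the mean
    for every feature is computed before anything is dropped.
    """
    if train_matrix.shape[0] < 3:
        raise ValidationError("correlation filter needs at least 3 training samples")
    if train_matrix.shape[1] < 2:
        raise ValidationError("correlation filter needs at least 2 features")
    if batch_size < 2:
        raise ValidationError("batch_size must be at least 2")
    values = train_matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("feature matrix contains non-finite values")

    n_feat = values.shape[1]
    mean_abs = np.empty(n_feat)
    for lo in range(0, n_feat, batch_size):
        hi = min(lo + batch_size, n_feat)
        mean_abs[lo:hi] = _batch_mean_abs_corr(values[:, lo:hi])

    series = pd.Series(mean_abs, index=train_matrix.columns, name="mean_abs_r")
    keep_mask = mean_abs <= threshold
    kept = list(train_matrix.columns[keep_mask])
    removed = list(train_matrix.columns[~keep_mask])
    return SelectionResult(
        kept_feature_ids=kept,
        removed_feature_ids=removed,
        mean_abs_corr=series,
        batch_size=batch_size,
        threshold=threshold,
    )


def iterative_correlation_filter(
    train_matrix: pd.DataFrame, batch_size: int = 1000, threshold: float = 0.7
) -> SelectionResult:
    """Greedy variant: repeat the single-pass filter on the survivors until
    no feature exceeds the threshold. Off by default in the pipeline."""
    current = train_matrix
    removed_all: list[str] = []
    while True:
        res = correlation_filter(current, batch_size=batch_size, threshold=threshold)
        removed_all.extend(res.removed_feature_ids)
        if not res.removed_feature_ids or len(res.kept_feature_ids) < 2:
            return SelectionResult(
                kept_feature_ids=res.kept_feature_ids,
                removed_feature_ids=removed_all,
                mean_abs_corr=res.mean_abs_corr,
                batch_size=batch_size,
                threshold=threshold,
            )
        current = current[res.kept_feature_ids]


def differential_test(train_matrix: pd.DataFrame, labels: list[str] | np.ndarray) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum (Mann-Whitney) test,
    cancer vs control.

    Returns a DataFrame indexed by feature id with ``statistic`` (the
    Mann-Whitney U of the cancer group) and ``pvalue``. Features constant
    across all samples carry p = 1 (no evidence against the null under any
    tie handling).
    """
    labels = np.asarray(labels)
    x = train_matrix.to_numpy(dtype=float)
    cancer = x[labels == "cancer"]
    control = x[labels == "control"]
    if cancer.shape[0] < 2 or control.shape[0] < 2:
        raise ValidationError("each label needs at least 2 samples")

    constant = np.ptp(x, axis=0) == 0
    stat = np.full(x.shape[1], np.nan)
    pval = np.ones(x.shape[1])
    varying = ~constant
    if varying.any():
        res = stats.mannwhitneyu(
            cancer[:, varying], control[:, varying], alternative="two-sided", axis=0
        )
        stat[varying] = res.statistic
        pval[varying] = res.pvalue
    stat[constant] = cancer.shape[0] * control.shape[0] / 2.0
    return pd.DataFrame(
        {"statistic": stat, "pvalue": pval}, index=train_matrix.columns
    )
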