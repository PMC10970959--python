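"""Shrinkage linear discriminant analysis and the evaluation metric panel.

The classifier is Gaussian LDA with a pooled within-class covariance
shrunk toward its own diagonal,

    sigma_hat = (1 - alpha) * S + alpha * diag(S),

which keeps per-feature variances untouched while damping the noisy
off-diagonal entries — mandatory in the p >> n regime of thousands of
region features and a few dozen training samples. The intensity ``alpha``
defaults to the Schafer-Strimmer analytic estimate for the diagonal
target; any fixed value in [0, 1] may be supplied instead.

Evaluation mirrors a diagnostic-test report: confusion counts, sensitivity
and specificity (overall, per tumor stage, per colon location, and for
early stages combined), and the rank-statistic AUC with ties counted 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CohortManifest, SampleMeta, ValidationError

CLASS_ORDER = ("control", "cancer")  # index 0 / 1; posterior is P(cancer)

#: Early clinical stages pooled for the combined early-stage sensitivity.
EARLY_STAGES = ("0", "I", "IIA")

#: Colon-segment -> group map; proximal and distal split at the splenic
#: flexure. Configurable in :func:`evaluate`.
DEFAULT_LOCATION_GROUPS = {
    "cecum": "proximal",
    "ileocecal valve": "proximal",
    "ascending colon": "proximal",
    "hepatic flexure": "proximal",
    "transverse colon": "proximal",
    "splenic flexure": "distal",
    "descending colon": "distal",
    "sigmoid colon": "distal",
    "rectosigmoid": "distal",
    "rectum": "distal",
}


class SingularCovarianceError(np.linalg.LinAlgError):
    """Raised when the unshrunk pooled covariance cannot be inverted."""


@dataclass
class LdaModel:
    feature_ids: list[str]
    mean_control: np.ndarray
    mean_cancer: np.ndarray
    coef: np.ndarray          # sigma_hat^{-1} (mu_cancer - mu_control)
    intercept: float
    shrinkage: float
    priors: tuple[float, float]  # (control, cancer)

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        return x @ self.coef + self.intercept

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "mean_control": self.mean_control,
                "mean_cancer": self.mean_cancer,
                "coef": self.coef,
            }
        )


def schafer_strimmer_alpha(residuals: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the diagonal target.

    ``residuals`` are the class-mean-centered observations (n x p). The
    intensity is the ratio of the summed sampling variances of the
    off-diagonal covariance entries to their summed squares, clipped to
    [0, 1].
    """
    n = residuals.shape[0]
    if n < 2:
        return 1.0
    w_mean = residuals.T @ residuals / n           # p x p, biased cov of residuals
    sq = residuals**2
    var_w = (sq.T @ sq) / n - w_mean**2            # Var of w_kij over k
    var_s = var_w * n / (n - 1) ** 3 * n           # unbiased-ish scaling to Var(s_ij)
    s = w_mean * n / (n - 1)
    off = ~np.eye(s.shape[0], dtype=bool)
    denom = float((s[off] ** 2).sum())
    if denom == 0.0:
        return 1.0
    alpha = float(var_s[off].sum()) / denom
    return float(np.clip(alpha, 0.0, 1.0))


def fit_lda(
    train_matrix: pd.DataFrame,
    labels: list[str] | np.ndarray,
    shrinkage: float | str = "auto",
    priors: tuple[float, float] | None = None,
) -> LdaModel:
    """Fit the diagonal-target shrinkage LDA on the training split.

    ``shrinkage`` is ``"auto"`` (Schafer-Strimmer estimate) or a fixed
    intensity in [0, 1]. Priors default to equal (0.5, 0.5), matching a
    diagnostic operating point independent of cohort composition.
    """
    labels = np.asarray(labels)
    x = train_matrix.to_numpy(dtype=float)
    n, p = x.shape
    if n < 4:
        raise ValidationError("LDA needs at least 4 training samples")
    for cls in CLASS_ORDER:
        if (labels == cls).sum() < 2:
            raise ValidationError(f"LDA needs at least 2 {cls!r} samples")

    mask_cancer = labels == "cancer"
    mu0 = x[~mask_cancer].mean(axis=0)
    mu1 = x[mask_cancer].mean(axis=0)
    residuals = x.copy()
    residuals[~mask_cancer] -= mu0
    residuals[mask_cancer] -= mu1
    # pooled within-class covariance, biased (/n) normalization: the overall
    # scale cancels in the decision rule and duplication-invariance holds
    s_pooled = residuals.T @ residuals / n

    if shrinkage == "auto":
        alpha = schafer_strimmer_alpha(residuals)
    else:
        alpha = float(shrinkage)
        if not 0.0 <= alpha <= 1.0:
            raise ValidationError(f"shrinkage must lie in [0, 1], got {alpha}")

    sigma = (1.0 - alpha) * s_pooled + alpha * np.diag(np.diag(s_pooled))
    delta = mu1 - mu0
    try:
        coef = np.linalg.solve(sigma, delta)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            f"pooled covariance is singular at shrinkage {alpha:g} "
            f"(p={p}, n={n}); supply shrinkage > 0 or 'auto'"
        ) from exc
    if p >= n and alpha == 0.0:
        raise SingularCovarianceError(
            f"pooled covariance is singular with p={p} >= n={n} at shrinkage 0; "
            "supply shrinkage > 0 or 'auto'"
        )

    if priors is None:
        priors = (0.5, 0.5)
    intercept = float(-coef @ (mu0 + mu1) / 2.0 + np.log(priors[1] / priors[0]))
    return LdaModel(
        feature_ids=list(train_matrix.columns),
        mean_control=mu0,
        mean_cancer=mu1,
        coef=coef,
        intercept=intercept,
        shrinkage=alpha,
        priors=priors,
    )


def score(model: LdaModel, matrix: pd.DataFrame) -> pd.Series:
    """Posterior probability of cancer per sample (strictly in (0, 1),
    monotone in the linear discriminant value)."""
    missing = [f for f in model.feature_ids if f not in matrix.columns]
    if missing:
        raise ValidationError(
            f"matrix lacks {len(missing)} model feature(s), e.g. {missing[:5]}"
        )
    x = matrix[model.feature_ids].to_numpy(dtype=float)
    d = model.decision_values(x)
    with np.errstate(over="ignore"):
        post = 1.0 / (1.0 + np.exp(-d))
    eps = np.finfo(float).eps
    post = np.clip(post, eps, 1.0 - eps)
    return pd.Series(post, index=matrix.index, name="posterior_cancer")


def auc_score(scores: np.ndarray | pd.Series, labels: list[str] | np.ndarray) -> float:
    """Rank-statistic AUC (Mann-Whitney concordance), ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == "cancer"
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class MetricsReport:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity_pct: float
    specificity_pct: float
    sensitivity_early_pct: float | None
    per_stage_sensitivity_pct: dict[str, float]
    per_location_sensitivity_pct: dict[str, float]
    per_group_sensitivity_pct: dict[str, float]
    auc: float
    threshold: float
    n_test: int

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.__dict__, indent=indent)

    def to_text(self) -> str:
        lines = [
            f"test samples: {self.n_test} "
            f"(cancer {self.tp + self.fn}, control {self.tn + self.fp})",
            f"confusion: TP={self.tp} FN={self.fn} TN={self.tn} FP={self.fp}",
            f"sensitivity: {self.sensitivity_pct:.1f}%  ({self.tp}/{self.tp + self.fn})",
            f"specificity: {self.specificity_pct:.1f}%  ({self.tn}/{self.tn + self.fp})",
            f"AUC: {self.auc:.3f}   (posterior threshold {self.threshold})",
        ]
        if self.sensitivity_early_pct is not None:
            lines.append(
                f"early-stage (0/I/IIA) sensitivity: {self.sensitivity_early_pct:.1f}%"
            )
        for name, d in (
            ("stage", self.per_stage_sensitivity_pct),
            ("location", self.per_location_sensitivity_pct),
            ("location group", self.per_group_sensitivity_pct),
        ):
            for k, v in d.items():
                lines.append(f"  sensitivity [{name} {k}]: {v:.1f}%")
        return "\n".join(lines)


def _subgroup_sensitivity(
    cancer_meta: list[SampleMeta], correct: dict[str, bool], key
) -> dict[str, float]:
    groups: dict[str, list[bool]] = {}
    for m in cancer_meta:
        k = key(m)
        if k is None or k == "NA":
            continue
        groups.setdefault(k, []).append(correct[m.sample_id])
    return {
        k: round(100.0 * sum(v) / len(v), 1) for k, v in sorted(groups.items())
    }


def evaluate(
    scores: pd.Series,
    test_manifest: CohortManifest,
    threshold: float = 0.5,
    location_groups: dict[str, str] | None = None,
) -> MetricsReport:
    """Confusion counts, sensitivities, specificity and AUC on the test split.

    A sample is called cancer when its posterior is >= ``threshold``.
    Percentages carry one decimal. Per-stage true positives always sum to
    the overall TP (every cancer sample has a stage).
    """
    metas = list(test_manifest)
    if not metas:
        raise ValidationError("empty test split")
    missing = [m.sample_id for m in metas if m.sample_id not in scores.index]
    if missing:
        raise ValidationError(f"no score for sample(s) {missing}")
    if location_groups is None:
        location_groups = DEFAULT_LOCATION_GROUPS

    labels = np.array([m.label for m in metas])
    s = scores.loc[[m.sample_id for m in metas]].to_numpy()
    called_cancer = s >= threshold
    is_cancer = labels == "cancer"

    tp = int((called_cancer & is_cancer).sum())
    fn = int((~called_cancer & is_cancer).sum())
    tn = int((~called_cancer & ~is_cancer).sum())
    fp = int((called_cancer & ~is_cancer).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("test split needs both cancer and control samples")

    correct = {
        m.sample_id: bool(c) for m, c in zip(metas, called_cancer)
    }
    cancer_meta = [m for m in metas if m.label == "cancer"]
    per_stage = _subgroup_sensitivity(cancer_meta, correct, lambda m: m.stage)
    per_location = _subgroup_sensitivity(cancer_meta, correct, lambda m: m.location)
    per_group = _subgroup_sensitivity(
        cancer_meta, correct, lambda m: location_groups.get(m.location)
    )

    early = [m for m in cancer_meta if m.stage in EARLY_STAGES]
    early_sens = (
        round(100.0 * sum(correct[m.sample_id] for m in early) / len(early), 1)
        if early
        else None
    )

    return MetricsReport(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity_pct=round(100.0 * tp / (tp + fn), 1),
        specificity_pct=round(100.0 * tn / (tn + fp), 1),
        sensitivity_early_pct=early_sens,
        per_stage_sensitivity_pct=per_stage,
        per_location_sensitivity_pct=per_location,
        per_group_sensitivity_pct=per_group,
        auc=round(auc_score(s, labels), 4),
        threshold=threshold,
        n_test=len(metas),
    )


def roc_points(scores: pd.Series | np.ndarray, labels: list[str] | np.ndarray) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) over all score cut points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == "cancer"
    order = np.argsort(-scores, kind="stable")
    thresholds = np.concatenate([[np.inf], scores[order]])
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    n1, n0 = int(pos.sum()), int((~pos).sum())
    for i in order:
        if pos[i]:
            tp += 1
        else:
            fp += 1
        tpr.append(tp / n1)
        fpr.append(fp / n0)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
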