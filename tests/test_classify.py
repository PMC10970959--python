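"""Shrinkage LDA, posterior scoring, AUC, and the metric panel."""

import numpy as np
import pandas as pd
import pytest

from fragcnv.classify import (
    MetricsReport,
    SingularCovarianceError,
    auc_score,
    evaluate,
    fit_lda,
    roc_points,
    score,
)
from fragcnv.core import CohortManifest, SampleMeta, ValidationError


def frame(x, prefix="f"):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return pd.DataFrame(x, columns=[f"{prefix}{i}" for i in range(x.shape[1])])


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == "cancer"]
    neg = scores[labels == "control"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestFitLda:
    def test_symmetric_1d_boundary_at_zero(self):
        x = frame(np.array([[-1.2], [-1.0], [-0.8], [0.8], [1.0], [1.2]]))
        labels = ["control"] * 3 + ["cancer"] * 3
        model = fit_lda(x, labels, shrinkage=0.0)
        posterior = score(model, frame([[0.0]]))
        assert posterior.iloc[0] == pytest.approx(0.5)
        assert score(model, frame([[1.0]])).iloc[0] > 0.5
        assert score(model, frame([[-1.0]])).iloc[0] < 0.5

    def test_duplicated_training_set_identical_parameters(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 4))
        labels = ["cancer"] * 6 + ["control"] * 6
        m1 = fit_lda(frame(x), labels, shrinkage=0.1)
        m2 = fit_lda(frame(np.vstack([x, x])), labels * 2, shrinkage=0.1)
        np.testing.assert_allclose(m1.coef, m2.coef)
        assert m1.intercept == pytest.approx(m2.intercept)

    def test_discriminant_direction_matches_analytic(self):
        """2-class Gaussian at n=200/class: fitted direction within 5 degrees
        of the closed-form sigma^-1 (mu1 - mu0)."""
        rng = np.random.default_rng(2)
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        mu0, mu1 = np.array([0.0, 0.0]), np.array([1.0, 0.5])
        chol = np.linalg.cholesky(cov)
        x0 = rng.normal(size=(200, 2)) @ chol.T + mu0
        x1 = rng.normal(size=(200, 2)) @ chol.T + mu1
        model = fit_lda(
            frame(np.vstack([x0, x1])), ["control"] * 200 + ["cancer"] * 200,
            shrinkage=0.0,
        )
        analytic = np.linalg.solve(cov, mu1 - mu0)
        cosine = model.coef @ analytic / (
            np.linalg.norm(model.coef) * np.linalg.norm(analytic)
        )
        assert np.degrees(np.arccos(np.clip(cosine, -1, 1))) < 5.0

    def test_singular_without_shrinkage_instructs_shrinkage(self):
        rng = np.random.default_rng(7)
        x = frame(rng.normal(size=(10, 40)))
        labels = ["cancer"] * 5 + ["control"] * 5
        with pytest.raises(SingularCovarianceError, match="shrinkage"):
            fit_lda(x, labels, shrinkage=0.0)
        model = fit_lda(x, labels, shrinkage="auto")
        assert 0.0 < model.shrinkage <= 1.0

    def test_matches_sklearn_on_well_conditioned_instance(self):
        """Cross-check against an independent LDA implementation: identical
        class calls and a near-parallel discriminant direction."""
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        rng = np.random.default_rng(11)
        x = np.vstack([
            rng.normal(0, 1, size=(60, 3)),
            rng.normal(0.8, 1, size=(60, 3)),
        ])
        labels = ["control"] * 60 + ["cancer"] * 60
        model = fit_lda(frame(x), labels, shrinkage=0.0)
        ours = score(model, frame(x)).to_numpy() >= 0.5

        sk = sklearn_lda(priors=[0.5, 0.5]).fit(x, labels)
        theirs = sk.predict(x) == "cancer"
        assert (ours == theirs).all()
        w = sk.coef_.ravel()
        cosine = model.coef @ w / (np.linalg.norm(model.coef) * np.linalg.norm(w))
        assert abs(cosine) > 0.9999

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            fit_lda(frame(np.eye(3)), ["cancer", "control", "cancer"])


class TestScore:
    def _model(self):
        rng = np.random.default_rng(13)
        x = np.vstack([rng.normal(-1, 1, (20, 2)), rng.normal(1, 1, (20, 2))])
        labels = ["control"] * 20 + ["cancer"] * 20
        return fit_lda(frame(x), labels, shrinkage=0.0)

    def test_class_mean_scores_toward_own_class(self):
        model = self._model()
        assert score(model, frame([model.mean_cancer])).iloc[0] > 0.5
        assert score(model, frame([model.mean_control])).iloc[0] < 0.5

    def test_midpoint_of_means_is_half(self):
        model = self._model()
        mid = (model.mean_cancer + model.mean_control) / 2
        assert score(model, frame([mid])).iloc[0] == pytest.approx(0.5)

    def test_feature_mismatch_listed(self):
        model = self._model()
        with pytest.raises(ValidationError, match="f1"):
            score(model, frame([[0.0]], prefix="f"))

    def test_posteriors_in_open_unit_interval(self):
        model = self._model()
        post = score(model, frame(np.array([[50.0, 50.0], [-50.0, -50.0]])))
        assert ((post > 0) & (post < 1)).all()


class TestAuc:
    def test_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 15))
            scores = rng.integers(0, 5, size=n).astype(float)  # many ties
            labels = np.where(rng.random(n) < 0.5, "cancer", "control")
            if len(set(labels)) < 2:
                continue
            assert auc_score(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(19)
        scores = rng.normal(size=40)
        labels = np.array(["cancer"] * 20 + ["control"] * 20)
        base = auc_score(scores, labels)
        assert auc_score(np.exp(scores), labels) == pytest.approx(base)
        assert auc_score(3 * scores - 7, labels) == pytest.approx(base)

    def test_perfect_separation_and_permutation_null(self):
        scores = np.concatenate([np.ones(10), np.zeros(10)])
        labels = np.array(["cancer"] * 10 + ["control"] * 10)
        assert auc_score(scores, labels) == 1.0

        rng = np.random.default_rng(23)
        sc = rng.normal(size=24)
        perm_labels = np.array(["cancer"] * 12 + ["control"] * 12)
        aucs = [
            auc_score(sc, rng.permutation(perm_labels)) for _ in range(10_000)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.02


def _test_manifest():
    metas = []
    stages = ["I"] * 4 + ["IIA"] * 4 + ["III"] * 4
    locations = [
        "rectum", "rectum", "ileocecal valve", "cecum",
        "hepatic flexure", "descending colon", "sigmoid colon", "transverse colon",
        "rectosigmoid", "cecum", "sigmoid colon", "transverse colon",
    ]
    for i, (st, loc) in enumerate(zip(stages, locations)):
        metas.append(
            SampleMeta(f"c{i}", "cancer", st, loc, "WGES", "test", f"c{i}.bed")
        )
    for i in range(12):
        metas.append(
            SampleMeta(f"n{i}", "control", "NA", "NA", "WGES", "test", f"n{i}.bed")
        )
    return CohortManifest(metas)


class TestEvaluate:
    def _scores(self, missed_cancer=("c0", "c8"), fp_control=("n0",)):
        """Posteriors reproducing a chosen confusion pattern."""
        manifest = _test_manifest()
        vals = {}
        for m in manifest:
            if m.label == "cancer":
                vals[m.sample_id] = 0.2 if m.sample_id in missed_cancer else 0.9
            else:
                vals[m.sample_id] = 0.8 if m.sample_id in fp_control else 0.1
        return pd.Series(vals), manifest

    def test_confusion_counts_to_percentages(self):
        """10/12 and 11/12 confusion counts give 83.3% sensitivity and
        91.7% specificity, printed as 83% / 92%."""
        scores, manifest = self._scores()
        rep = evaluate(scores, manifest)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (10, 2, 11, 1)
        assert rep.sensitivity_pct == 83.3
        assert rep.specificity_pct == 91.7
        assert round(rep.sensitivity_pct) == 83
        assert round(rep.specificity_pct) == 92

    def test_per_stage_and_early_combined(self):
        """Stage I 3/4 = 75%, stage IIA 4/4 = 100%, early stages combined
        7/8 = 87.5%, stage III 3/4 = 75%."""
        scores, manifest = self._scores()
        rep = evaluate(scores, manifest)
        assert rep.per_stage_sensitivity_pct == {"I": 75.0, "IIA": 100.0, "III": 75.0}
        assert rep.sensitivity_early_pct == 87.5

    def test_per_stage_tp_sums_to_overall(self):
        scores, manifest = self._scores()
        rep = evaluate(scores, manifest)
        stage_counts = {"I": 4, "IIA": 4, "III": 4}
        tp_from_stages = sum(
            rep.per_stage_sensitivity_pct[s] / 100 * n for s, n in stage_counts.items()
        )
        assert tp_from_stages == pytest.approx(rep.tp)

    def test_location_groups(self):
        scores, manifest = self._scores(missed_cancer=("c2", "c8"))
        rep = evaluate(scores, manifest)
        # c2 (ileocecal valve) is proximal, c8 (rectosigmoid) distal: 5/6 each
        assert rep.per_group_sensitivity_pct == {"distal": 83.3, "proximal": 83.3}

    def test_auc_and_roc(self):
        scores, manifest = self._scores()
        rep = evaluate(scores, manifest)
        assert rep.auc == pytest.approx(
            brute_force_auc(
                scores.loc[manifest.sample_ids()], np.array(manifest.labels())
            ),
            abs=1e-4,
        )
        roc = roc_points(scores.loc[manifest.sample_ids()], manifest.labels())
        assert roc["tpr"].iloc[0] == 0.0 and roc["tpr"].iloc[-1] == 1.0
        assert roc["fpr"].iloc[-1] == 1.0

    def test_empty_split_rejected(self):
        with pytest.raises(ValidationError):
            evaluate(pd.Series(dtype=float), CohortManifest([]))

    def test_json_roundtrip(self):
        scores, manifest = self._scores()
        rep = evaluate(scores, manifest)
        import json

        parsed = json.loads(rep.to_json())
        assert parsed["sensitivity_pct"] == 83.3
        assert MetricsReport(**parsed).tp == 10
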