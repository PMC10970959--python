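"""Correlation-based region filtering and the per-region rank-sum test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fragcnv.core import ValidationError
from fragcnv.selection import (
    correlation_filter,
    differential_test,
    iterative_correlation_filter,
)
from fragcnv.simulate import SampleSpec, simulate_fragment_arrays


def matrix(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values, columns=[f"{prefix}{i}" for i in range(values.shape[1])]
    )


class TestCorrelationFilter:
    def test_independent_noise_keeps_everything(self):
        rng = np.random.default_rng(11)
        m = matrix(rng.normal(size=(48, 100)))
        res = correlation_filter(m, batch_size=1000, threshold=0.7)
        assert res.removed_feature_ids == []
        assert (res.mean_abs_corr < 0.5).all()

    def test_duplicate_pair_bruteforce_oracle(self):
        """f0 == f1 duplicated, f2 independent: mean |r| of f0/f1 is
        (1 + |r02|)/2 — verified against per-pair Pearson computed directly."""
        rng = np.random.default_rng(13)
        x = rng.normal(size=48)
        z = rng.normal(size=48)
        m = matrix(np.column_stack([x, x, z]))
        res = correlation_filter(m, threshold=0.7)
        r02 = abs(stats.pearsonr(x, z)[0])
        r12 = abs(stats.pearsonr(x, z)[0])
        expected = {
            "f0": (1 + r02) / 2,
            "f1": (1 + r12) / 2,
            "f2": (r02 + r12) / 2,
        }
        for f, v in expected.items():
            assert res.mean_abs_corr[f] == pytest.approx(v)
        assert res.removed_feature_ids == []  # (1 + ~0)/2 < 0.7
        res_tight = correlation_filter(m, threshold=0.4)
        assert set(res_tight.removed_feature_ids) == {"f0", "f1"}
        assert res_tight.kept_feature_ids == ["f2"]

    def test_threshold_one_removes_nothing(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=10)
        m = matrix(np.column_stack([x, x, -x]))
        res = correlation_filter(m, threshold=1.0)
        assert res.removed_feature_ids == []

    def test_constant_feature_kept_with_zero_mean(self):
        rng = np.random.default_rng(29)
        m = matrix(np.column_stack([np.ones(20), rng.normal(size=20), rng.normal(size=20)]))
        res = correlation_filter(m, threshold=0.7)
        assert res.mean_abs_corr["f0"] == 0.0
        assert "f0" in res.kept_feature_ids

    def test_batching_is_consecutive(self):
        """Identical columns placed in different batches are not compared:
        with batch_size 2, the pairs (f0,f1) and (f2,f3) are each within one
        batch but f1/f2 are not."""
        rng = np.random.default_rng(31)
        x, y = rng.normal(size=20), rng.normal(size=20)
        m = matrix(np.column_stack([x, x, y, y]))
        res = correlation_filter(m, batch_size=2, threshold=0.7)
        assert set(res.removed_feature_ids) == {"f0", "f1", "f2", "f3"}
        assert res.mean_abs_corr["f0"] == pytest.approx(1.0)

    def test_single_pass_simultaneous_removal_permutation_invariant(self):
        rng = np.random.default_rng(37)
        base = rng.normal(size=(30, 8))
        base[:, 1] = base[:, 0] + rng.normal(0, 0.05, 30)
        base[:, 5] = base[:, 4] + rng.normal(0, 0.05, 30)
        m = matrix(base)
        res = correlation_filter(m, threshold=0.4)
        perm = list(rng.permutation(m.columns))
        res_p = correlation_filter(m[perm], threshold=0.4)
        assert set(res.removed_feature_ids) == set(res_p.removed_feature_ids)

    def test_idempotent_on_random_instances(self):
        rng = np.random.default_rng(41)
        for trial in range(5):
            x = rng.normal(size=(25, 12))
            for j in range(0, 12, 4):
                x[:, j + 1] = x[:, j] + rng.normal(0, 0.1, 25)
            m = matrix(x)
            res = correlation_filter(m, threshold=0.5)
            again = correlation_filter(m[res.kept_feature_ids], threshold=0.5)
            assert again.removed_feature_ids == []

    def test_kept_features_respect_threshold(self):
        rng = np.random.default_rng(43)
        m = matrix(rng.normal(size=(20, 30)))
        res = correlation_filter(m, batch_size=10, threshold=0.3)
        assert (res.mean_abs_corr[res.kept_feature_ids] <= 0.3).all()
        assert (res.mean_abs_corr[res.removed_feature_ids] > 0.3).all()
        assert set(res.kept_feature_ids) | set(res.removed_feature_ids) == set(m.columns)

    def test_too_few_samples_or_features_rejected(self):
        rng = np.random.default_rng(47)
        with pytest.raises(ValidationError):
            correlation_filter(matrix(rng.normal(size=(2, 5))))
        with pytest.raises(ValidationError):
            correlation_filter(matrix(rng.normal(size=(10, 1))))

    def test_non_finite_rejected(self):
        m = matrix([[1.0, 2.0], [3.0, np.nan], [1.0, 0.5]])
        with pytest.raises(ValidationError, match="non-finite"):
            correlation_filter(m)

    def test_iterative_variant_terminates_and_is_at_most_single_pass(self):
        rng = np.random.default_rng(53)
        x = rng.normal(size=(30, 10))
        x[:, 1] = x[:, 0]
        m = matrix(x)
        res_it = iterative_correlation_filter(m, threshold=0.4)
        res_sp = correlation_filter(m, threshold=0.4)
        assert set(res_it.kept_feature_ids) <= set(res_sp.kept_feature_ids) | set(
            res_sp.removed_feature_ids
        )


class TestDifferentialTest:
    def test_identical_values_give_p_one(self):
        m = matrix(np.ones((10, 3)))
        labels = ["cancer"] * 5 + ["control"] * 5
        res = differential_test(m, labels)
        assert (res["pvalue"] == 1.0).all()

    def test_complete_separation_exact_p(self):
        """5 cancer values all above 5 controls: two-sided exact p = 2/252,
        verified by enumerating all C(10,5) label assignments."""
        vals = np.array([10.0, 11, 12, 13, 14, 1, 2, 3, 4, 5])
        m = matrix(vals[:, None])
        labels = ["cancer"] * 5 + ["control"] * 5
        res = differential_test(m, labels)
        assert res["pvalue"].iloc[0] == pytest.approx(2 / 252)

        # enumeration oracle: how many assignments give a rank-sum statistic
        # at least as extreme (two-sided) as observed
        ranks = stats.rankdata(vals)
        obs = ranks[:5].sum()
        mean = ranks.sum() / 2
        count = sum(
            abs(sum(ranks[list(c)]) - mean) >= abs(obs - mean) - 1e-9
            for c in itertools.combinations(range(10), 5)
        )
        assert count / math.comb(10, 5) == pytest.approx(2 / 252)

    def test_cnv_bin_has_smallest_p_across_replicates(self, flat_genome):
        """With one strongly amplified bin, the per-region rank-sum test
        ranks that bin most significant in at least 19 of 20 replicates."""
        hits = 0
        cnv_bin = 120
        for rep in range(20):
            rows = []
            labels = []
            for k in range(24):
                cancer = k < 12
                spec = SampleSpec(
                    label="cancer" if cancer else "control",
                    tumor_fraction=0.2 if cancer else 0.0,
                    chemistry="WGS",
                    n_fragments=20_000,
                    seed=10_000 + 100 * rep + k,
                    cnv_bins=(cnv_bin,) if cancer else (),
                    cnv_copy_ratio=3.0,
                )
                s, e = simulate_fragment_arrays(flat_genome, spec)
                lengths = e - s
                in_class = (lengths >= 100) & (lengths <= 220)
                mids = (s + e) // 2
                counts = np.bincount(
                    mids[in_class] // 5000, minlength=flat_genome.n_bins
                ).astype(float)
                rows.append(counts / counts.sum() * 1e6)
                labels.append("cancer" if cancer else "control")
            res = differential_test(matrix(np.array(rows), prefix="bin"), labels)
            if res["pvalue"].idxmin() == f"bin{cnv_bin}":
                hits += 1
        assert hits >= 19

    def test_small_group_rejected(self):
        m = matrix(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValidationError):
            differential_test(m, ["cancer", "control", "control", "control"])
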