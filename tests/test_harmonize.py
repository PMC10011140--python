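"""Expression QC, TMM normalization, covariate regression, PCA, kNN."""

import numpy as np
import pandas as pd
import pytest

from eqtlkit import harmonize
from eqtlkit.harmonize import ExpressionMatrix

from conftest import build_custom_study


def _em(values, scale="log2", genes=None, samples=None):
    df = pd.DataFrame(values,
                      index=genes or [f"g{i}" for i in range(values.shape[0])],
                      columns=samples or [f"s{i}" for i in range(values.shape[1])])
    return ExpressionMatrix(df, scale=scale)


class TestQcFilter:
    def test_manual_five_sample_oracle(self):
        metrics = pd.DataFrame({
            "pct_coding_bases": [0.05, 0.50, 0.12, 0.10, 0.40],
            "pct_reads_aligned": [0.90, 0.50, 0.80, 0.70, 0.95],
            "pct_unique_mapping": [0.90, 0.90, 0.55, 0.80, 0.85],
        }, index=[f"s{i}" for i in range(5)])
        kept = harmonize.qc_filter_samples(metrics)
        # s0 fails coding bases (5% < 10%), s1 fails alignment, s2 fails
        # unique mapping; s3 sits exactly on the coding-bases threshold and
        # is retained (exclusion is strict-less-than)
        assert list(kept) == ["s3", "s4"]

    def test_missing_column_raises(self):
        metrics = pd.DataFrame({"pct_coding_bases": [0.5]}, index=["s0"])
        with pytest.raises(ValueError, match="pct_reads_aligned"):
            harmonize.qc_filter_samples(metrics)


class TestTmm:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.poisson(40, 100).astype(float) + 1
        em = _em(np.column_stack([col] * 4), scale="counts")
        out = harmonize.tmm_normalize(em)
        assert np.allclose(out.provenance["tmm_factors"], 1.0)

    def test_pure_depth_difference(self, rng):
        a = rng.poisson(60, 300).astype(float) + 1
        em = _em(np.column_stack([a, 2 * a]), scale="counts")
        out = harmonize.tmm_normalize(em)
        assert np.allclose(out.values.iloc[:, 0], out.values.iloc[:, 1],
                           atol=1e-9)

    def test_hand_computed_factor_oracle(self, rng):
        """Step-by-step M/A trimming computation reproduced independently."""
        counts = (rng.poisson(100, size=(80, 2)).astype(float) + 1)
        counts[:10, 1] *= 4  # asymmetric DE genes
        em = _em(counts, scale="counts")
        out = harmonize.tmm_normalize(em, trim_m=0.3, trim_a=0.05)
        factors = np.array(out.provenance["tmm_factors"])

        obs, ref = counts[:, 0], counts[:, 1]  # column 1 has higher depth
        no, nr = obs.sum(), ref.sum()
        o, r = obs / no, ref / nr
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        lo_m, hi_m = np.quantile(m, [0.3, 0.7])
        lo_a, hi_a = np.quantile(a, [0.05, 0.95])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        w = 1.0 / ((no - obs) / (no * obs) + (nr - ref) / (nr * ref))
        f0 = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
        expected = np.array([f0, 1.0])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(factors, expected, rtol=1e-9)

    def test_input_validation(self, rng):
        em = _em(rng.poisson(10, (20, 3)).astype(float), scale="log2")
        with pytest.raises(ValueError):
            harmonize.tmm_normalize(em)
        z = rng.poisson(10, (20, 3)).astype(float)
        z[:, 1] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            harmonize.tmm_normalize(_em(z, scale="counts"))


class TestCovariateRegression:
    def test_orthogonal_covariate_noop(self, rng):
        Y = rng.normal(0, 1, (40, 60))
        em = _em(Y)
        # covariate orthogonalized against the intercept and every gene
        c = rng.normal(0, 1, 60)
        X = np.column_stack([np.ones(60), Y.T])
        c -= X @ np.linalg.lstsq(X, c, rcond=None)[0]
        covs = pd.DataFrame({"c": c}, index=em.samples)
        out = harmonize.regress_top_covariates(em, covs, k=1)
        assert np.allclose(out.values.to_numpy(), Y, atol=1e-9)

    def test_exact_removal(self, rng):
        c = rng.normal(0, 1, 80)
        Y = np.outer(np.full(30, 2.0), c) + rng.normal(0, 0.01, (30, 80))
        em = _em(Y)
        covs = pd.DataFrame({"c": c}, index=em.samples)
        out = harmonize.regress_top_covariates(em, covs, k=1)
        for row in out.values.to_numpy():
            assert abs(np.corrcoef(row, c)[0, 1]) < 1e-6

    def test_batch_shift_shrinks_and_pc1_decorrelates(self):
        st = build_custom_study(n_per_cohort=(80, 80), seed=51,
                                batch_effect_sd=3.0, noise_sd=0.4,
                                n_genes=40, n_variants=60)
        joint = pd.concat([c.expression for c in st.cohorts], axis=1)
        covs = pd.concat([c.covariates for c in st.cohorts])
        cohort = np.repeat([0.0, 1.0], 80)
        em = ExpressionMatrix(joint, scale="log2")
        before = np.abs(joint.to_numpy()[:, :80].mean(axis=1)
                        - joint.to_numpy()[:, 80:].mean(axis=1))
        out = harmonize.regress_top_covariates(em, covs, k=2)
        Y = out.values.to_numpy()
        after = np.abs(Y[:, :80].mean(axis=1) - Y[:, 80:].mean(axis=1))
        assert after.mean() < before.mean() / 10
        scores = harmonize.pca_samples(out, n_pcs=2)
        r = np.corrcoef(scores["PC1"], cohort)[0, 1]
        assert abs(r) < 0.2

    def test_collinear_covariates_dropped(self, rng):
        Y = rng.normal(0, 1, (20, 30))
        em = _em(Y)
        c = rng.normal(0, 1, 30)
        covs = pd.DataFrame({"a": c, "b": 2 * c}, index=em.samples)
        out = harmonize.regress_top_covariates(em, covs, k=2)
        assert len(out.provenance["covariates_removed"]) == 1


class TestPca:
    def test_duplicate_samples_identical_scores(self, rng):
        Y = rng.normal(0, 1, (50, 10))
        Y[:, 1] = Y[:, 0]
        scores = harmonize.pca_samples(_em(Y), n_pcs=3)
        assert np.allclose(scores.iloc[0], scores.iloc[1], atol=1e-8)

    def test_eigenvalue_trace_and_order(self, rng):
        Y = rng.normal(0, 1, (60, 25))
        scores = harmonize.pca_samples(_em(Y), n_pcs=5)
        ev = scores.attrs["eigenvalues"]
        assert ev.sum() == pytest.approx(25, abs=1e-6)
        assert np.all(np.diff(ev) <= 1e-10)

    def test_two_clusters_separate_on_pc1(self, rng):
        Y = rng.normal(0, 1, (100, 40))
        Y[:50, 20:] += 4.0  # half the genes upregulated in cluster 2
        scores = harmonize.pca_samples(_em(Y), n_pcs=2)
        pc1 = scores["PC1"].to_numpy()
        assert (max(pc1[:20]) < min(pc1[20:])
                or min(pc1[:20]) > max(pc1[20:]))

    def test_constant_sample_raises(self, rng):
        Y = rng.normal(0, 1, (30, 5))
        Y[:, 2] = 7.0
        with pytest.raises(ValueError, match="constant"):
            harmonize.pca_samples(_em(Y))


class TestKnn:
    def test_unanimous_and_majority(self):
        pts = pd.DataFrame({"PC1": np.arange(10.0), "PC2": 0.0},
                           index=[f"l{i}" for i in range(10)])
        labels = pd.Series(["cortex"] * 7 + ["cerebellum"] * 3,
                           index=pts.index)
        q = pd.DataFrame({"PC1": [0.1], "PC2": [0.0]}, index=["q"])
        assert harmonize.knn_classify_region(q, pts, labels).iloc[0] == "cortex"
        labels2 = pd.Series(["cortex"] * 5 + ["cerebellum"] * 5,
                            index=pts.index)
        # 7 nearest to PC1=0.1 are l0..l6: 5 cortex / 2 cerebellum
        assert harmonize.knn_classify_region(q, pts, labels2).iloc[0] == "cortex"

    def test_brute_force_oracle(self, rng):
        ref = pd.DataFrame(rng.normal(0, 1, (10, 2)),
                           columns=["PC1", "PC2"],
                           index=[f"l{i}" for i in range(10)])
        labels = pd.Series(rng.choice(["a", "b", "c"], 10), index=ref.index)
        q = pd.DataFrame(rng.normal(0, 1, (15, 2)), columns=["PC1", "PC2"],
                         index=[f"q{i}" for i in range(15)])
        got = harmonize.knn_classify_region(q, ref, labels, k=7)
        for i in range(15):
            d = np.sqrt(((ref.to_numpy() - q.to_numpy()[i]) ** 2).sum(axis=1))
            nn = np.argsort(d, kind="mergesort")[:7]
            counts = {}
            for j in nn:
                c, w = counts.get(labels.iloc[j], (0, 0.0))
                counts[labels.iloc[j]] = (c + 1, w + 1 / max(d[j], 1e-12))
            best = sorted(counts.items(),
                          key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))[0][0]
            assert got.iloc[i] == best

    def test_k_exceeds_labeled_raises(self):
        pts = pd.DataFrame({"PC1": [0.0], "PC2": [0.0]}, index=["l0"])
        labels = pd.Series(["a"], index=pts.index)
        with pytest.raises(ValueError):
            harmonize.knn_classify_region(pts, pts, labels, k=7)


class TestPcCorrection:
    def test_identity_at_zero_and_orthogonality(self, rng):
        Y = rng.normal(0, 1, (40, 50))
        em = _em(Y)
        out0 = harmonize.pc_correct_expression(em, 0)
        assert np.array_equal(out0.values.to_numpy(), Y)
        out = harmonize.pc_correct_expression(em, 5)
        scores = harmonize.expression_pcs(em, 5)
        for j in range(5):
            pc = scores.iloc[:, j].to_numpy()
            for row in out.values.to_numpy()[:10]:
                r = np.corrcoef(row, pc)[0, 1]
                assert abs(r) < 1e-8

    def test_trans_factor_removed(self, rng):
        n, g = 100, 50
        factor = rng.normal(0, 1, n)
        loadings = rng.normal(0, 1, g)
        Y = np.outer(loadings, factor) * 2 + rng.normal(0, 1, (g, n))
        em = _em(Y)
        corr_before = np.abs(np.corrcoef(Y)).mean()
        out = harmonize.pc_correct_expression(em, 5)
        corr_after = np.abs(np.corrcoef(out.values.to_numpy())
                            [np.triu_indices(g, 1)]).mean()
        assert corr_after < 0.1
        assert out.provenance["n_pcs_removed"] == 5

    def test_shapes_and_errors(self, rng):
        em = _em(rng.normal(0, 1, (10, 8)))
        out = harmonize.pc_correct_expression(em, 3)
        assert out.values.shape == em.values.shape
        assert list(out.values.index) == list(em.values.index)
        with pytest.raises(ValueError):
            harmonize.pc_correct_expression(em, 8)


class TestOutlierFlagging:
    def test_extreme_sample_flagged(self, rng):
        Y = rng.normal(0, 1, (60, 40))
        em = _em(Y)
        scores = harmonize.pca_samples(em, 4)
        scores.iloc[0] = scores.iloc[0] + 50.0
        kept = harmonize.flag_pca_outliers(scores)
        assert scores.index[0] not in kept
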