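"""Association engine: HWE, filters, pair building, Spearman meta-analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eqtlkit import meta, synth

from conftest import build_custom_study, nearest_variant


class TestHwe:
    def test_equilibrium_and_het_deficit(self):
        assert meta.hwe_exact_p(25, 50, 25) >= 0.5
        assert meta.hwe_exact_p(50, 0, 50) < 1e-20

    def test_exhaustive_enumeration_oracle(self):
        """p(60,20,20) equals direct enumeration over all het counts with the
        allele totals fixed (independent log-gamma implementation)."""
        def oracle(nAA, nAB, nBB):
            n = nAA + nAB + nBB
            rare = min(2 * nAA + nAB, 2 * n - (2 * nAA + nAB))
            hets = list(range(rare % 2, rare + 1, 2))
            logs = []
            for h in hets:
                hr = (rare - h) // 2
                logs.append(math.lgamma(n + 1) - math.lgamma(hr + 1)
                            - math.lgamma(h + 1)
                            - math.lgamma(n - h - hr + 1) + h * math.log(2))
            pr = np.exp(np.array(logs) - max(logs))
            pr /= pr.sum()
            obs = pr[hets.index(nAB)]
            return min(pr[pr <= obs * (1 + 1e-9)].sum(), 1.0)

        for table in [(60, 20, 20), (5, 10, 5), (0, 1, 0), (30, 10, 1)]:
            assert meta.hwe_exact_p(*table) == pytest.approx(
                oracle(*table), abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            meta.hwe_exact_p(-1, 2, 3)
        with pytest.raises(ValueError):
            meta.hwe_exact_p(0, 0, 0)


class TestVariantFilters:
    def test_manual_filter_oracle(self):
        qc = pd.DataFrame({
            "maf": [0.30, 0.005, 0.0, 0.20, 0.45, 0.02, 0.3, 0.1, 0.25, 0.4],
            "hwe_p": [0.5, 0.5, 0.5, 1e-5, 0.5, 0.5, 1e-4, 0.9, 0.3, 0.2],
            "missingness": [0.0, 0.0, 0.0, 0.0, 0.5, 0.0, 0.0, 0.0, 0.04, 0.06],
        }, index=[f"v{i}" for i in range(10)])
        keep, dropped = meta.filter_variants(qc, maf_min=0.01, hwe_min=1e-4,
                                             max_missing=0.05)
        # hand application: v1 (maf), v2 (monomorphic), v3 (hwe), v4 (miss),
        # v6 (hwe boundary: p > threshold required), v9 (miss) fail
        assert list(keep) == ["v0", "v5", "v7", "v8"]
        assert set(dropped["variant"]) == {"v1", "v2", "v3", "v4", "v6", "v9"}

    def test_qc_table_weighted_maf(self):
        g1 = synth.simulate_genotypes(300, 10, seed=1)
        g2 = synth.simulate_genotypes(100, 10, seed=2,
                                      variant_meta=g1.variants)
        qc = meta.variant_qc_table([g1, g2])
        expect = (300 * g1.observed_maf() + 100 * g2.observed_maf()) / 400
        assert np.allclose(qc["maf"].to_numpy(), expect)


@pytest.fixture(scope="module")
def toy():
    variants = pd.DataFrame({
        "chrom": ["chr1"] * 4 + ["chr2"],
        "pos": [1_000_000, 1_999_999, 2_000_001, 9_000_000, 1_500_000],
        "ref": "A", "alt": "G",
    }, index=[f"v{i}" for i in range(5)])
    genes = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "tss": [1_000_000, 7_000_000, 1_400_000],
        "strand": ["+", "-", "+"],
        "biotype": ["protein_coding", "lncRNA", "protein_coding"],
    }, index=["gA", "gB", "gC"])
    return variants, genes


class TestPairs:
    def test_window_boundary(self, toy):
        variants, genes = toy
        pairs = meta.cis_pairs(variants, genes, window=1_000_000)
        ga = set(pairs[pairs.gene == "gA"]["variant"])
        assert "v1" in ga       # 999,999 bp away
        assert "v2" not in ga   # 1,000,001 bp away

    def test_biotype_filter_and_strand_sign(self, toy):
        variants, genes = toy
        pairs = meta.cis_pairs(variants, genes)
        assert "gB" not in set(pairs.gene)  # lncRNA excluded by default
        allpairs = meta.cis_pairs(variants, genes, window=3_000_000,
                                  biotype_filter=None)
        assert "gB" in set(allpairs.gene)
        d = pairs[(pairs.gene == "gC") & (pairs.variant == "v4")]
        assert int(d.distance.iloc[0]) == 100_000

    def test_brute_force_pair_oracle(self, default_study):
        st = default_study
        pairs = meta.cis_pairs(st.variants, st.genes, window=500_000)
        expected = set()
        for gene, g in st.genes[st.genes.biotype == "protein_coding"].iterrows():
            for v, vr in st.variants.iterrows():
                if vr.chrom == g.chrom and abs(vr.pos - g.tss) <= 500_000:
                    expected.add((gene, v))
        assert set(zip(pairs.gene, pairs.variant)) == expected

    def test_trans_rule_boundary(self, toy):
        variants, genes = toy
        # gB at 7 Mb: v0 at 1 Mb -> 6 Mb away (included); v3 at 9 Mb ->
        # 2 Mb away (excluded); different chromosome always included
        tp = meta.trans_pairs(variants, genes, ["v0", "v3", "v4"],
                              biotype_filter=None)
        gb = set(tp[tp.gene == "gB"]["variant"])
        assert "v0" in gb and "v3" not in gb and "v4" in gb


class TestAssociation:
    def test_monotone_pair_hits_cap(self, rng):
        x = np.arange(50, dtype=float)
        y = x ** 2
        n, rho, z = meta.cohort_assoc(x, y)
        assert rho == pytest.approx(1.0)
        assert z == pytest.approx(meta.Z_CAP)

    def test_rank_formula_oracle_with_ties(self, rng):
        d = rng.binomial(2, 0.4, 40).astype(float)
        e = rng.normal(0, 1, 40)
        _, rho, _ = meta.cohort_assoc(d, e)
        rd = sps.rankdata(d)
        re = sps.rankdata(e)
        oracle = np.corrcoef(rd, re)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_null_z_standard_normal(self, rng):
        n = 200
        D = rng.binomial(2, 0.3, size=(n, 2000)).astype(float)
        y = rng.normal(0, 1, n)
        _, _, zs = meta.assoc_block(D, y)
        assert sps.kstest(zs, "norm").pvalue > 0.01

    def test_small_cohort_and_constant_vector_skipped(self):
        assert meta.cohort_assoc(np.ones(50), np.arange(50.0)) is None
        assert meta.cohort_assoc(np.arange(10.0), np.arange(10.0)) is None


class TestMetaZ:
    def test_single_cohort_identity_and_cancellation(self):
        z, p, n = meta.meta_z([(100, 2.0)])
        assert z == pytest.approx(2.0)
        z, _, _ = meta.meta_z([(100, 1.0), (100, -1.0)])
        assert z == pytest.approx(0.0)

    def test_weighted_formula(self):
        z, p, n = meta.meta_z([(100, 2.0), (400, 3.0)])
        assert z == pytest.approx(80.0 / math.sqrt(500.0), abs=1e-9)
        assert n == 500
        assert p == pytest.approx(2 * sps.norm.sf(z), abs=1e-12)

    def test_cohort_order_invariance_exact(self):
        stats = [(130, 1.3), (77, -0.4), (512, 2.2), (31, 0.9)]
        z0, _, _ = meta.meta_z(stats)
        z1, _, _ = meta.meta_z(stats[::-1])
        assert z0 == z1


class TestZtoBeta:
    def test_null_and_arithmetic(self):
        b, se = meta.zscore_to_beta_se(0.0, 0.25, 1000)
        assert b == 0.0
        assert se == pytest.approx(1 / math.sqrt(2 * 0.25 * 0.75 * 1000))
        b, se = meta.zscore_to_beta_se(5.0, 0.3, 1000)
        d = math.sqrt(2 * 0.3 * 0.7 * 1025)
        assert b == pytest.approx(5 / d, abs=1e-4)
        assert b == pytest.approx(0.2410, abs=2e-4)
        assert se == pytest.approx(0.04820, abs=5e-5)

    def test_self_consistency_and_errors(self, rng):
        for _ in range(20):
            z = rng.normal(0, 3)
            maf = rng.uniform(0.01, 0.5)
            n = rng.integers(50, 5000)
            b, se = meta.zscore_to_beta_se(z, maf, n)
            assert b / se == pytest.approx(z, abs=1e-12)
        with pytest.raises(ValueError):
            meta.zscore_to_beta_se(1.0, 0.0, 100)


class TestRunScan:
    def test_allele_swap_harmonization_invariance(self):
        st = build_custom_study(n_per_cohort=(150, 150), seed=7,
                                allele_flip_rate=0.0)
        gene = "GENE0003"
        v = nearest_variant(st, gene)
        st_flip = build_custom_study(n_per_cohort=(150, 150), seed=7,
                                     allele_flip_rate=0.5)
        pairs = meta.cis_pairs(st.variants, st.genes)
        pairs = pairs[pairs.gene == gene]
        a = meta.run_scan(st.cohorts, pairs)
        b = meta.run_scan(st_flip.cohorts, pairs)
        m = a.merge(b, on=["gene", "variant"], suffixes=("_a", "_b"))
        assert np.allclose(m.meta_z_a, m.meta_z_b, atol=1e-9)

    def test_planted_cis_is_top_hit_across_seeds(self):
        hits = 0
        for s in range(10):
            st0 = build_custom_study(n_per_cohort=(300, 300), seed=40 + s)
            coding = st0.genes[(st0.genes.biotype == "protein_coding")
                               & ~st0.genes.index.str.startswith("MK_")]
            gene = coding.index[0]
            v = nearest_variant(st0, gene)
            st = build_custom_study(planted_cis=[(v, gene, 0.5)],
                                    n_per_cohort=(300, 300), seed=40 + s)
            pairs = meta.cis_pairs(st.variants, st.genes)
            pairs = pairs[pairs.gene == gene]
            scan = meta.run_scan(st.cohorts, pairs)
            top = scan.loc[scan.p.idxmin(), "variant"]
            if top == v:
                hits += 1
            else:  # credit LD proxies of the planted variant
                pooled = np.concatenate(
                    [c.genotypes.dosage_of(v, complete=True)
                     for c in st.cohorts])
                other = np.concatenate(
                    [c.genotypes.dosage_of(top, complete=True)
                     for c in st.cohorts])
                if np.corrcoef(pooled, other)[0, 1] ** 2 > 0.5:
                    hits += 1
        assert hits >= 9

    def test_null_scan_type_i_error(self):
        st = build_custom_study(n_per_cohort=(200, 200), seed=13,
                                n_variants=200, n_genes=40)
        pairs = meta.cis_pairs(st.variants, st.genes)
        scan = meta.run_scan(st.cohorts, pairs)
        frac = float((scan.meta_z.abs() > 1.96).mean())
        # LD makes pairs dependent; allow a generous band around 5%
        se = math.sqrt(0.05 * 0.95 / len(scan))
        assert abs(frac - 0.05) < max(3 * se, 0.03)

    def test_split_cohort_consistency(self):
        st0 = build_custom_study(n_per_cohort=(400,), seed=17)
        gene = "GENE0006"
        v = nearest_variant(st0, gene)
        st = build_custom_study(planted_cis=[(v, gene, 0.5)],
                                n_per_cohort=(400,), seed=17)
        pairs = meta.cis_pairs(st.variants, st.genes)
        pairs = pairs[(pairs.gene == gene) & (pairs.variant == v)]
        full = meta.run_scan(st.cohorts, pairs)
        c = st.cohorts[0]
        half1 = synth.CohortDataset(
            "h1", synth.GenotypeMatrix(c.genotypes.dosages[:200],
                                       c.genotypes.variants,
                                       c.genotypes.samples[:200]),
            c.expression.iloc[:, :200], c.covariates.iloc[:200],
            c.proportions.iloc[:200])
        half2 = synth.CohortDataset(
            "h2", synth.GenotypeMatrix(c.genotypes.dosages[200:],
                                       c.genotypes.variants,
                                       c.genotypes.samples[200:]),
            c.expression.iloc[:, 200:], c.covariates.iloc[200:],
            c.proportions.iloc[200:])
        split = meta.run_scan([half1, half2], pairs)
        assert abs(float(full.meta_z.iloc[0])
                   - float(split.meta_z.iloc[0])) < 0.2
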