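import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boargwas import postgwas
from boargwas.types import ExpressionMatrix, GeneAnnotation, GenotypeData
from oracles import haplotype_counting_r2


def _genes(rows):
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])
    )


def _hits(rows):
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos"])


def _geno_from_dosages(dosages, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    mm = pd.DataFrame(
        {
            "marker": [f"m{j}" for j in range(m)],
            "chrom": [chrom] * m,
            "pos": positions or list(np.arange(1, m + 1) * 1000),
            "allele_a": ["A"] * m,
            "allele_b": ["G"] * m,
        }
    )
    return GenotypeData(dosages, mm, [f"an{i}" for i in range(dosages.shape[0])])


class TestAnnotateGenes:
    def test_gene_within_window_with_distance(self):
        hits = _hits([("m1", "1", 5_000_000)])
        genes = _genes([("gA", "1", 4_200_000, 4_300_000)])
        out = postgwas.annotate_genes(hits, genes)
        assert out[0].genes["gene_id"].tolist() == ["gA"]
        assert out[0].genes["distance_bp"].iloc[0] == 700_000

    def test_window_clamped_at_chromosome_start(self):
        out = postgwas.annotate_genes(
            _hits([("m1", "1", 400_000)]), _genes([("gA", "1", 10, 20)])
        )
        assert out[0].window_start == 1
        assert out[0].window_end == 1_400_000

    def test_inclusive_boundary(self):
        # gene ending exactly at window_start is included
        hits = _hits([("m1", "1", 5_000_000)])
        genes = _genes([("gA", "1", 3_900_000, 4_000_000)])
        out = postgwas.annotate_genes(hits, genes)
        assert len(out[0].genes) == 1
        genes2 = _genes([("gA", "1", 3_900_000, 3_999_999)])
        assert len(postgwas.annotate_genes(hits, genes2)[0].genes) == 0

    def test_unknown_chromosome_yields_empty_list(self):
        out = postgwas.annotate_genes(
            _hits([("m1", "99", 1_000_000)]), _genes([("gA", "1", 10, 20)])
        )
        assert len(out[0].genes) == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            genes_rows = [
                (f"g{i}", str(rng.integers(1, 3)),
                 int(s := rng.integers(1, 9_000_000)),
                 int(s + rng.integers(1, 500_000)))
                for i in range(30)
            ]
            hits_rows = [
                (f"m{i}", str(rng.integers(1, 3)), int(rng.integers(1, 9_000_000)))
                for i in range(5)
            ]
            out = postgwas.annotate_genes(_hits(hits_rows), _genes(genes_rows))
            for hit, (mk, ch, pos) in zip(out, hits_rows):
                expect = {
                    g for g, c, s, e in genes_rows
                    if c == ch and e >= max(1, pos - 1_000_000)
                    and s <= pos + 1_000_000
                }
                assert set(hit.genes["gene_id"]) == expect


class TestCisEqtl:
    def test_perfect_signal_recovers_marker(self):
        rng = np.random.default_rng(13)
        d = (rng.random((50, 5)) < 0.4).astype(float) + (rng.random((50, 5)) < 0.4)
        geno = _geno_from_dosages(d)
        expr = ExpressionMatrix(
            "testis", pd.DataFrame({a: [d[i, 2]] for i, a in
                                    enumerate(geno.animal_ids)}, index=["gX"])
        )
        genes = _genes([("gX", "1", 2500, 3500)])
        out = postgwas.cis_eqtl_scan(expr, geno, genes, log_transform=False)
        top = out.sort_values("p").iloc[0]
        assert top["marker"] == "m2"
        assert top["beta"] == pytest.approx(1.0)
        assert top["p"] <= np.finfo(float).tiny

    def test_marker_outside_cis_window_absent(self):
        rng = np.random.default_rng(14)
        d = (rng.random((40, 2)) < 0.4).astype(float) + (rng.random((40, 2)) < 0.4)
        geno = _geno_from_dosages(d, positions=[1000, 5_000_000])
        expr = ExpressionMatrix(
            "testis",
            pd.DataFrame(
                {a: [rng.random()] for a in geno.animal_ids}, index=["gX"]
            ),
        )
        genes = _genes([("gX", "1", 500, 2000)])
        out = postgwas.cis_eqtl_scan(expr, geno, genes, cis_window_bp=100_000)
        assert set(out["marker"]) == {"m0"}

    def test_permutation_null_is_uniform(self):
        rng = np.random.default_rng(15)
        n, m = 100, 60
        d = (rng.random((n, m)) < 0.3).astype(float) + (rng.random((n, m)) < 0.3)
        geno = _geno_from_dosages(d)
        values = pd.DataFrame(
            rng.standard_normal((30, n)) + 5.0,
            index=[f"g{i}" for i in range(30)],
            columns=geno.animal_ids,
        )
        expr = ExpressionMatrix("testis", values)
        genes = _genes(
            [(f"g{i}", "1", 1 + i * 2000, 1500 + i * 2000) for i in range(30)]
        )
        out = postgwas.cis_eqtl_scan(expr, geno, genes, cis_window_bp=30_000)
        assert len(out) > 500
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01


class TestLd:
    def test_identical_markers_r2_one(self):
        rng = np.random.default_rng(16)
        x = (rng.random(200) < 0.3).astype(float) + (rng.random(200) < 0.3)
        geno = _geno_from_dosages(np.column_stack([x, x]))
        pair = postgwas.ld_r2(geno, "m0", "m1")
        assert pair.r2 == pytest.approx(1.0, abs=1e-9)

    def test_em_equals_counting_without_double_heterozygotes(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = 300
            h1a = (rng.random(n) < 0.4).astype(int)
            h1b = np.where(rng.random(n) < 0.8, h1a, 1 - h1a)  # correlated
            h2a = (rng.random(n) < 0.4).astype(int)
            h2b = np.where(rng.random(n) < 0.8, h2a, 1 - h2a)
            ga, gb = h1a + h2a, h1b + h2b
            keep = ~((ga == 1) & (gb == 1))  # drop double heterozygotes
            if len(np.unique(ga[keep])) < 2 or len(np.unique(gb[keep])) < 2:
                continue
            geno = _geno_from_dosages(
                np.column_stack([ga[keep], gb[keep]]).astype(float)
            )
            pair = postgwas.ld_r2(geno, "m0", "m1")
            oracle = haplotype_counting_r2(
                np.concatenate([h1a[keep], h2a[keep]]),
                np.concatenate([h1b[keep], h2b[keep]]),
            )
            assert pair.r2 == pytest.approx(oracle, abs=1e-9)

    def test_independent_markers_low_r2(self):
        rng = np.random.default_rng(18)
        n = 500
        r2s = []
        for _ in range(20):
            d = (rng.random((n, 2)) < 0.4).astype(float) + (rng.random((n, 2)) < 0.4)
            geno = _geno_from_dosages(d)
            r2s.append(postgwas.ld_r2(geno, "m0", "m1").r2)
        assert np.mean(r2s) < 0.02

    def test_monomorphic_errors(self):
        d = np.column_stack([np.ones(10), np.zeros(10)])
        d[0, 0] = 0.0
        with pytest.raises(ValueError, match="monomorphic"):
            postgwas.ld_r2(_geno_from_dosages(d), "m0", "m1")


class TestLsd:
    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(19)
        y0 = rng.standard_normal(12)
        y1 = rng.standard_normal(15) + 0.5
        res = postgwas.lsd_genotype_expression(
            np.concatenate([y0, y1]), np.array([0] * 12 + [1] * 15)
        )
        t_ref = stats.ttest_ind(y1, y0, equal_var=True)
        assert res.pairwise["p"].iloc[0] == pytest.approx(t_ref.pvalue, abs=1e-12)

    def test_constant_groups_flagged_degenerate(self):
        res = postgwas.lsd_genotype_expression(
            np.array([1.0, 1.0, 1.0, 1.0]), np.array([0, 0, 1, 1])
        )
        assert res.degenerate

    def test_requires_two_sizable_classes(self):
        with pytest.raises(ValueError):
            postgwas.lsd_genotype_expression(
                np.array([1.0, 2.0, 3.0]), np.array([0, 0, 1])
            )

    def test_additive_effect_detected_across_genotypes(self):
        rng = np.random.default_rng(20)
        hits = 0
        for _ in range(25):
            y = np.concatenate(
                [rng.standard_normal(30) + shift for shift in (0.0, 1.0, 2.0)]
            )
            g = np.repeat([0, 1, 2], 30)
            res = postgwas.lsd_genotype_expression(y, g)
            if (res.pairwise["p"] < 0.05).all():
                hits += 1
        assert hits >= 23

    def test_stars_convention(self):
        assert postgwas._stars(0.2) == "ns"
        assert postgwas._stars(0.04) == "*"
        assert postgwas._stars(0.005) == "**"
        assert postgwas._stars(0.0005) == "***"


class TestColocalize:
    def _setup(self, rng, r2_high=True):
        n = 400
        h_a = (rng.random(n) < 0.4).astype(int)
        h_a2 = (rng.random(n) < 0.4).astype(int)
        flip_rate = 0.02 if r2_high else 0.5
        h_b = np.where(rng.random(n) < 1 - flip_rate, h_a, 1 - h_a)
        h_b2 = np.where(rng.random(n) < 1 - flip_rate, h_a2, 1 - h_a2)
        ga = h_a + h_a2
        gb = h_b + h_b2
        geno = _geno_from_dosages(
            np.column_stack([ga, gb]).astype(float), positions=[1000, 2000]
        )
        genes = _genes([("gX", "1", 500, 2500)])
        return geno, genes

    def test_direct_overlap(self):
        rng = np.random.default_rng(21)
        geno, genes = self._setup(rng)
        hits = _hits([("m0", "1", 1000)])
        eqtls = pd.DataFrame(
            [{"gene_id": "gX", "marker": "m0", "tissue": "testis",
              "beta": 1.0, "se": 0.1, "p": 1e-10, "n_samples": 400}]
        )
        out = postgwas.colocalize(hits, eqtls, geno, genes)
        assert len(out) == 1
        assert out.iloc[0]["mechanism"] == "direct"
        assert out.iloc[0]["r2"] == 1.0

    def test_ld_mediated(self):
        rng = np.random.default_rng(22)
        geno, genes = self._setup(rng, r2_high=True)
        pair = postgwas.ld_r2(geno, "m0", "m1")
        assert pair.r2 > 0.8  # engineered tight-LD neighbor
        hits = _hits([("m0", "1", 1000)])
        eqtls = pd.DataFrame(
            [{"gene_id": "gX", "marker": "m1", "tissue": "testis",
              "beta": 1.0, "se": 0.1, "p": 1e-10, "n_samples": 400}]
        )
        out = postgwas.colocalize(hits, eqtls, geno, genes)
        assert len(out) == 1
        assert out.iloc[0]["mechanism"] == "ld"
        assert out.iloc[0]["r2"] == pytest.approx(pair.r2)

    def test_gene_outside_window_not_reported(self):
        rng = np.random.default_rng(23)
        geno, genes = self._setup(rng)
        far_genes = _genes([("gX", "1", 5_000_000, 5_020_000)])
        hits = _hits([("m0", "1", 1000)])
        eqtls = pd.DataFrame(
            [{"gene_id": "gX", "marker": "m0", "tissue": "testis",
              "beta": 1.0, "se": 0.1, "p": 1e-10, "n_samples": 400}]
        )
        out = postgwas.colocalize(hits, eqtls, geno, far_genes, window_bp=100_000)
        assert out.empty
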