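"""SNP-adjacency windows, bootstrap enrichment, disease-specific
proportions, and hypergeometric module/DE overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncnet import genetics as gen

from conftest import toy_annotation


def _snps(positions, chrom="chr1", labels=None):
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(len(positions))],
        "chrom": chrom, "position": positions,
        "disease": labels or ["shared"] * len(positions)})


class TestSnpAdjacency:
    def test_window_boundaries(self):
        annotation = toy_annotation([("G1", "lncRNA", "chr1", 100_000, 120_000)])
        amap = gen.snp_adjacent_genes(annotation, _snps([50_000, 49_999,
                                                         169_999, 170_000]))
        assert amap["G1"] == ["rs0", "rs2"]

    def test_window_clamped_at_zero(self):
        annotation = toy_annotation([("G1", "lncRNA", "chr1", 10_000, 12_000)])
        amap = gen.snp_adjacent_genes(annotation, _snps([0]))
        assert amap["G1"] == ["rs0"]

    def test_chromosome_mismatch(self):
        annotation = toy_annotation([("G1", "lncRNA", "chr2", 100_000, 120_000)])
        amap = gen.snp_adjacent_genes(annotation, _snps([110_000], chrom="chr1"))
        assert amap["G1"] == []


class TestBootstrapEnrichment:
    def _setup(self, rng, n=400, frac_lnc=0.5, p_adj=0.1):
        gene_ids = [f"G{i}" for i in range(n)]
        biotypes = np.where(rng.random(n) < frac_lnc, "lncRNA", "protein_coding")
        annotation = toy_annotation(
            [(g, b, "chr1", i * 1000, i * 1000 + 500)
             for i, (g, b) in enumerate(zip(gene_ids, biotypes))])
        amap = {g: (["rs0"] if rng.random() < p_adj else []) for g in gene_ids}
        return annotation, pd.Index(gene_ids), amap

    def test_module_equal_to_universe_p_one(self, rng):
        annotation, universe, amap = self._setup(rng)
        res = gen.bootstrap_enrichment(universe, universe, amap, annotation,
                                       n_boot=500, seed=0)
        assert res.p_value["lncRNA"] == 1.0
        assert res.p_value["protein_coding"] == 1.0

    def test_fully_adjacent_module_strongly_enriched(self, rng):
        annotation, universe, amap = self._setup(rng)
        adj_lnc = [g for g in universe
                   if amap[g] and annotation.set_index("gene_id")
                   .loc[g, "biotype"] == "lncRNA"]
        module = adj_lnc[:15]
        res = gen.bootstrap_enrichment(module, universe, amap, annotation,
                                       n_boot=10_000, seed=1)
        assert res.observed["lncRNA"] == 1.0
        assert res.p_value["lncRNA"] <= 0.001

    def test_missing_biotype_gives_missing_p(self, rng):
        annotation, universe, amap = self._setup(rng)
        bt = annotation.set_index("gene_id")["biotype"]
        module = [g for g in universe if bt[g] == "lncRNA"][:20]
        res = gen.bootstrap_enrichment(module, universe, amap, annotation,
                                       n_boot=200, seed=2)
        assert np.isnan(res.p_value["protein_coding"])

    def test_module_outside_universe_rejected(self, rng):
        annotation, universe, amap = self._setup(rng)
        with pytest.raises(ValueError):
            gen.bootstrap_enrichment(["NOPE"], universe, amap, annotation)

    def test_p_decreases_with_enrichment_odds(self, rng):
        annotation, universe, amap = self._setup(rng, n=600)
        bt = annotation.set_index("gene_id")["biotype"]
        lncs = [g for g in universe if bt[g] == "lncRNA"]
        pvals = []
        for odds in (1.0, 3.0, 9.0):
            p_bg = 0.1
            p_mod = odds * p_bg / (1 - p_bg) / (1 + odds * p_bg / (1 - p_bg))
            r = np.random.default_rng(int(odds * 10))
            amap_o = dict(amap)
            module = lncs[:50]
            for g in module:
                amap_o[g] = ["rs0"] if r.random() < p_mod else []
            res = gen.bootstrap_enrichment(module, universe, amap_o, annotation,
                                           n_boot=5000, seed=3)
            pvals.append(res.p_value["lncRNA"])
        assert pvals[0] > pvals[-1]
        assert sorted(pvals, reverse=True) == pvals or pvals[1] <= pvals[0]


class TestDiseaseProportions:
    def _amap(self, labels_per_gene):
        snps = []
        amap = {}
        for i, (g, labels) in enumerate(labels_per_gene.items()):
            ids = []
            for j, lab in enumerate(labels):
                sid = f"rs{i}_{j}"
                snps.append({"snp_id": sid, "chrom": "chr1",
                             "position": 0, "disease": lab})
            ids = [s["snp_id"] for s in snps if s["snp_id"].startswith(f"rs{i}_")]
            amap[g] = ids
        return amap, pd.DataFrame(snps)

    def test_all_uc(self):
        amap, snps = self._amap({f"L{i}": ["UC-specific"] for i in range(4)})
        out = gen.disease_specific_proportions({"m": list(amap)}, amap, snps)
        assert out.loc["m", "uc_fraction"] == 1.0

    def test_below_min_count_omitted(self):
        amap, snps = self._amap({"L0": ["UC-specific"], "L1": ["CD-specific"]})
        out = gen.disease_specific_proportions({"m": list(amap)}, amap, snps)
        assert "m" not in out.index

    def test_mixed_three_one(self):
        amap, snps = self._amap({f"L{i}": ["UC-specific"] for i in range(3)}
                                | {"L3": ["CD-specific"]})
        out = gen.disease_specific_proportions({"m": list(amap)}, amap, snps)
        assert out.loc["m", "uc_fraction"] == 0.75
        assert out.loc["m", "cd_fraction"] == 0.25

    def test_shared_only_genes_not_counted(self):
        amap, snps = self._amap({f"L{i}": ["shared"] for i in range(5)})
        out = gen.disease_specific_proportions({"m": list(amap)}, amap, snps)
        assert len(out) == 0


class TestModuleDeOverlap:
    def test_disjoint_sets_p_near_one(self):
        _, p = gen.module_de_overlap([f"a{i}" for i in range(5)],
                                     [f"b{i}" for i in range(4)], 20)
        assert p == pytest.approx(1.0)

    def test_hand_computed_tail(self):
        # N=20, K=5, n=4, overlap=3
        module = [f"m{i}" for i in range(5)]
        de = module[:3] + ["x"]
        overlap, p = gen.module_de_overlap(module, de, 20)
        assert overlap == 3
        from math import comb
        expected = (comb(5, 3) * comb(15, 1) + comb(5, 4)) / comb(20, 4)
        assert p == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(0.0320, abs=5e-4)

    def test_identical_sets_minimal_p(self):
        module = [f"m{i}" for i in range(5)]
        _, p_same = gen.module_de_overlap(module, module, 30)
        _, p_less = gen.module_de_overlap(module, module[:4] + ["z"], 30)
        assert p_same < p_less

    def test_equals_fisher_exact(self, rng):
        for _ in range(200):
            N = int(rng.integers(10, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            module = [f"g{i}" for i in range(K)]
            de = module[:k] + [f"x{i}" for i in range(n - k)]
            _, p = gen.module_de_overlap(module, de, N)
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            _, p_fisher = stats.fisher_exact(table, alternative="greater")
            assert p == pytest.approx(p_fisher, abs=1e-10)

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            gen.module_de_overlap(["a"], ["a"], 0)
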