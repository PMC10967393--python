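"""Eigengenes, merging, kME, intramodular connectivity, trait correlation,
and module composition."""

import numpy as np
import pandas as pd
import pytest

from lncnet import module_analysis as ma
from lncnet import network as nw
from lncnet.expression import ExpressionMatrix

from conftest import toy_annotation


def _em(values, meta=None):
    vals = pd.DataFrame(np.asarray(values, dtype=float))
    vals.index = [f"S{i}" for i in range(len(vals))]
    vals.columns = [f"G{i}" for i in range(vals.shape[1])]
    if meta is None:
        meta = pd.DataFrame(index=vals.index)
    return ExpressionMatrix(vals, meta, scale="logTPM")


def _assignment(labels, genes):
    return nw.ModuleAssignment(pd.Series(labels, index=genes, name="module"))


class TestEigengenes:
    def test_identical_genes_variance_explained_one(self, rng):
        profile = rng.standard_normal(30)
        vals = np.tile(profile[:, None], (1, 5))
        em = _em(vals)
        asg = _assignment(["blue"] * 5, em.genes)
        mes = ma.eigengenes(em, asg)
        assert mes.variance_explained["blue"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(mes.scores["blue"], z, atol=1e-10)

    def test_anticorrelated_pair_oriented_by_mean(self, rng):
        x = rng.standard_normal(40)
        em = _em(np.column_stack([x, -x]))
        mes = ma.eigengenes(em, _assignment(["m"] * 2, em.genes))
        assert mes.variance_explained["m"] == pytest.approx(1.0)

    def test_matches_svd_oracle(self, rng):
        vals = rng.standard_normal((50, 12))
        em = _em(vals)
        mes = ma.eigengenes(em, _assignment(["m"] * 12, em.genes))
        X = (vals - vals.mean(0)) / vals.std(0)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        oracle = U[:, 0] * S[0]
        oracle /= oracle.std()
        if np.corrcoef(oracle, X.mean(1))[0, 1] < 0:
            oracle = -oracle
        assert np.allclose(mes.scores["m"], oracle, atol=1e-10)
        assert mes.variance_explained["m"] == pytest.approx(
            S[0] ** 2 / (S ** 2).sum(), abs=1e-10)

    def test_constant_module_rejected(self):
        em = _em(np.ones((10, 3)))
        with pytest.raises(ValueError):
            ma.eigengenes(em, _assignment(["m"] * 3, em.genes))


class TestMerge:
    def _mes_with_correlation(self, rho, rng, n=400):
        base = rng.standard_normal(n)
        other = rho * base + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        # build expression whose two modules have eigengenes base/other
        g1 = base[:, None] + 0.05 * rng.standard_normal((n, 10))
        g2 = other[:, None] + 0.05 * rng.standard_normal((n, 8))
        em = _em(np.column_stack([g1, g2]))
        asg = _assignment(["big"] * 10 + ["small"] * 8, em.genes)
        return em, asg, ma.eigengenes(em, asg)

    def test_high_correlation_merges_into_larger(self, rng):
        em, asg, mes = self._mes_with_correlation(0.95, rng)
        merged, _, lineage = ma.merge_modules(mes, asg, em)
        assert len(merged.modules) == 1
        assert lineage["small"] == "big"

    def test_low_correlation_not_merged(self, rng):
        em, asg, mes = self._mes_with_correlation(0.5, rng)
        merged, _, _ = ma.merge_modules(mes, asg, em)
        assert len(merged.modules) == 2

    def test_merging_monotone_in_cut_height(self, small_network):
        resid, _, assignment = small_network
        mes = ma.eigengenes(resid, assignment)
        counts = []
        for h in (0.05, 0.2, 0.5, 0.9):
            merged, _, _ = ma.merge_modules(mes, assignment, resid, cut_height=h)
            counts.append(len(merged.modules))
        assert counts == sorted(counts, reverse=True)


class TestKme:
    def test_gene_equal_to_eigengene(self, rng):
        x = rng.standard_normal(60)
        em = _em(np.column_stack([x, x + 0.01 * rng.standard_normal(60), -x]))
        asg = _assignment(["m", "m", "m"], em.genes)
        mes = ma.eigengenes(em, asg)
        k = ma.kme(em, mes)
        assert abs(k.loc["G0", "m"]) > 0.999
        assert k.loc["G2", "m"] == pytest.approx(-k.loc["G0", "m"], abs=1e-6)

    def test_own_module_kme_dominates_on_planted_data(self, small_modules,
                                                      small_cohort):
        resid, _, merged, mes = small_modules
        k = ma.kme(resid, mes)
        labels = merged.labels
        wins = 0
        module_genes = labels[labels != nw.GREY]
        for g, mod in module_genes.items():
            wins += k.loc[g].abs().idxmax() == mod
        assert wins / len(module_genes) >= 0.95

    def test_independent_gene_small_kme(self, rng):
        n = 500
        x = rng.standard_normal(n)
        vals = np.column_stack([x + 0.1 * rng.standard_normal(n)
                                for _ in range(5)])
        indep = rng.standard_normal(n)
        em = _em(np.column_stack([vals, indep]))
        asg = _assignment(["m"] * 5 + [nw.GREY], em.genes)
        k = ma.kme(em, ma.eigengenes(em, asg))
        assert abs(k.loc["G5", "m"]) < 0.15


class TestIntramodularConnectivity:
    def test_hand_value_and_oracle(self, rng):
        n = 9
        r = rng.uniform(-1, 1, (n, n))
        a = np.abs((r + r.T) / 2)
        np.fill_diagonal(a, 1.0)
        genes = pd.Index([f"g{i}" for i in range(n)])
        net = nw.CoexpressionNetwork(genes, a, 1, a, a.sum(1) - 1)
        labels = ["m1"] * 4 + ["m2"] * 5
        kim = ma.intramodular_connectivity(net, _assignment(labels, genes))
        for i in range(n):
            same = [j for j in range(n) if labels[j] == labels[i] and j != i]
            assert kim.iloc[i] == pytest.approx(sum(a[i, j] for j in same))

    def test_uniform_small_module(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        genes = pd.Index(list("abc"))
        net = nw.CoexpressionNetwork(genes, a, 1, a, a.sum(1) - 1)
        kim = ma.intramodular_connectivity(net, _assignment(["m"] * 3, genes))
        assert np.allclose(kim, 1.0)


class TestTraitCorrelation:
    def test_trait_equal_to_eigengene(self, small_modules):
        resid, _, merged, mes = small_modules
        mod = mes.scores.columns[0]
        traits = pd.DataFrame({"self": mes.scores[mod]})
        r, p, stars = ma.module_trait_correlation(mes, traits)
        assert r.loc[mod, "self"] == pytest.approx(1.0)
        assert stars.loc[mod, "self"] == "***"

    def test_short_trait_left_missing(self, small_modules):
        _, _, _, mes = small_modules
        t = pd.Series(np.nan, index=mes.scores.index)
        t.iloc[:2] = [1.0, 2.0]
        r, p, _ = ma.module_trait_correlation(mes, pd.DataFrame({"t": t}))
        assert r["t"].isna().all()

    def test_star_rule(self):
        assert ma._stars(0.04) == "*"
        assert ma._stars(0.009) == "**"
        assert ma._stars(0.0009) == "***"
        assert ma._stars(0.05) == ""

    def test_planted_trait_effect_recovered(self, small_modules, small_cohort):
        from lncnet.synthetic import trait_design
        resid, _, merged, mes = small_modules
        _, _, meta, _, truth = small_cohort
        traits = trait_design(meta).loc[resid.samples]
        r, _, _ = ma.module_trait_correlation(mes, traits)
        # the inflammation-driven planted module should correlate clearly
        assert r["inflamed"].abs().max() > 0.3


class TestGeneTraitSignificance:
    def test_gene_equal_to_trait(self, rng):
        x = rng.standard_normal(50)
        em = _em(np.column_stack([x, rng.standard_normal(50)]))
        gs = ma.gene_trait_significance(em, pd.Series(x, index=em.samples))
        assert gs["G0"] == pytest.approx(1.0)

    def test_constant_gene_missing(self):
        em = _em(np.column_stack([np.ones(10), np.arange(10.0)]))
        gs = ma.gene_trait_significance(
            em, pd.Series(np.arange(10.0), index=em.samples))
        assert np.isnan(gs["G0"]) and gs["G1"] == pytest.approx(1.0)


class TestComposition:
    def test_pure_lncRNA_module(self):
        annotation = toy_annotation([("L1", "lncRNA", "chr1", 0, 1000),
                                     ("L2", "lncRNA", "chr1", 5000, 6000)])
        asg = _assignment(["m", "m"], pd.Index(["L1", "L2"]))
        comp = ma.module_composition(asg, annotation)
        assert comp.loc["m", "lncRNA_fraction"] == 1.0

    @pytest.mark.parametrize("gap,expected", [(49_999, 1.0), (50_001, 0.0)])
    def test_proximity_boundary(self, gap, expected):
        # lncRNA body ends at 1000; coding gene starts 'gap' bp later
        annotation = toy_annotation([
            ("L1", "lncRNA", "chr1", 0, 1000),
            ("P1", "protein_coding", "chr1", 1000 + gap, 1000 + gap + 500)])
        asg = _assignment(["m", "m"], pd.Index(["L1", "P1"]))
        comp = ma.module_composition(asg, annotation)
        assert comp.loc["m", "lnc_near_coding_fraction"] == expected
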