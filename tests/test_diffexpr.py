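"""Zero-inflated Gaussian DE: model collapse to OLS, fallback behavior,
BH adjustment, DE calling, and set overlap."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lncnet import diffexpr as de
from lncnet.expression import ExpressionMatrix


def _meta(n, rng, diseases=("HC", "UC"), batches=3):
    meta = pd.DataFrame({
        "disease": rng.choice(diseases, n),
        "batch": rng.choice([f"B{i}" for i in range(batches)], n),
        "patient": [f"P{i}" for i in range(n)],
        "tissue": "rectum",
    }, index=[f"S{i}" for i in range(n)])
    meta["inflamed"] = np.where(
        meta["disease"] == "HC", "no", rng.choice(["yes", "no"], n))
    return meta


def _simulate(meta, beta, rng, sigma=1.0, zero_frac=0.0, batch_sd=0.0):
    grp = de.disease_inflammation_group(meta)
    batch_eff = {b: rng.normal(0, batch_sd)
                 for b in meta["batch"].unique()} if batch_sd else {}
    y = (5.0 + beta * (grp == "UC-inf").astype(float)
         + meta["batch"].map(batch_eff).fillna(0.0)
         + rng.normal(0, sigma, len(meta)))
    if zero_frac:
        y = y.where(rng.random(len(meta)) >= zero_frac, 0.0)
    return pd.Series(np.maximum(y.values, 0.0), index=meta.index)


class TestFitZig:
    def test_no_zeros_no_random_effects_equals_ols(self, rng):
        meta = _meta(120, rng)
        y = _simulate(meta, 0.8, rng)
        spec = de.DeModelSpec(contrast="UC-inf", random_effects=())
        fit = de.fit_zig(y, meta, spec)
        grp = de.disease_inflammation_group(meta)
        X = pd.get_dummies(grp, dtype=float).drop(columns="HC-noninf")
        res = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.lfc == pytest.approx(res.params["UC-inf"], abs=1e-8)
        assert fit.model_used == "zig"

    def test_all_zero_gene_excluded(self, rng):
        meta = _meta(40, rng)
        fit = de.fit_zig(pd.Series(0.0, index=meta.index), meta,
                         de.DeModelSpec())
        assert fit.model_used == "excluded"

    def test_sparse_groups_excluded(self, rng):
        meta = _meta(40, rng)
        y = pd.Series(0.0, index=meta.index)
        y.iloc[:4] = 1.0  # nonzero in effectively one group
        meta2 = meta.copy()
        meta2.loc[y.index[:4], ["disease", "inflamed"]] = ["UC", "yes"]
        fit = de.fit_zig(y, meta2, de.DeModelSpec())
        assert fit.model_used == "excluded"

    def test_zero_relabeling_leaves_continuous_part_invariant(self, rng):
        # hurdle factorization: continuous coefficients depend only on y>0
        meta = _meta(150, rng)
        y = _simulate(meta, 1.0, rng, zero_frac=0.3)
        spec = de.DeModelSpec(contrast="UC-inf", random_effects=("batch",))
        with_zero_part = de.fit_zig(y, meta, spec, zero_part=True)
        without = de.fit_zig(y, meta, spec, zero_part=False)
        assert with_zero_part.lfc == pytest.approx(without.lfc, abs=1e-12)
        assert with_zero_part.p == pytest.approx(without.p, abs=1e-12)

    def test_recovery_with_batch_random_effect(self, rng):
        ests = []
        for rep in range(25):
            r = np.random.default_rng(1000 + rep)
            meta = _meta(300, r)
            y = _simulate(meta, 1.0, r, zero_frac=0.3, batch_sd=0.5)
            fit = de.fit_zig(y, meta, de.DeModelSpec(contrast="UC-inf"))
            ests.append(fit.lfc)
        assert np.mean(ests) == pytest.approx(1.0, abs=0.1)


class TestFallback:
    def test_no_random_effects_is_ols_on_all_observations(self, rng):
        meta = _meta(100, rng)
        y = _simulate(meta, 0.5, rng, zero_frac=0.2)
        spec = de.DeModelSpec(contrast="UC-inf", random_effects=())
        fit = de.fit_lmm_fallback(y, meta, spec)
        grp = de.disease_inflammation_group(meta)
        X = pd.get_dummies(grp, dtype=float).drop(columns="HC-noninf")
        res = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.lfc == pytest.approx(res.params["UC-inf"], abs=1e-8)
        assert fit.model_used == "lmm_fallback"

    def test_vanishing_noise_recovers_group_difference(self, rng):
        meta = _meta(60, rng)
        y = _simulate(meta, 1.0, rng, sigma=1e-8)
        spec = de.DeModelSpec(contrast="UC-inf", random_effects=())
        fit = de.fit_lmm_fallback(y, meta, spec)
        assert fit.lfc == pytest.approx(1.0, abs=1e-6)


class TestRunDe:
    def _expr(self, rng, n=80, n_genes=6, beta=0.0):
        meta = _meta(n, rng)
        vals = pd.DataFrame(
            {f"G{i}": _simulate(meta, beta, rng, zero_frac=0.2)
             for i in range(n_genes)})
        return ExpressionMatrix(vals, meta, scale="logTPM"), meta

    def _annotation(self, genes):
        from conftest import toy_annotation
        return toy_annotation([(g, "lncRNA", "chr1", i * 1000, i * 1000 + 100)
                               for i, g in enumerate(genes)])

    def test_location_random_effect_structure(self):
        assert de.LOCATION_RANDOM_EFFECTS["colon_nonrectal"] == ("patient", "batch")
        assert de.LOCATION_RANDOM_EFFECTS["ileum"] == ("batch",)

    def test_unknown_location_rejected(self, rng):
        expr, _ = self._expr(rng)
        with pytest.raises(KeyError):
            de.run_de(expr, self._annotation(expr.genes), de.DeModelSpec(),
                      "duodenum")

    def test_output_schema_and_bh(self, rng):
        expr, _ = self._expr(rng)
        out = de.run_de(expr, self._annotation(expr.genes),
                        de.DeModelSpec(contrast="UC-inf"), "rectum")
        assert {"biotype", "lfc", "se", "p", "p_adj", "model_used"} <= set(out)
        ok = out["p"].notna()
        assert (out.loc[ok, "p_adj"] >= out.loc[ok, "p"] - 1e-12).all()
        assert out.loc[ok, "p_adj"].between(0, 1).all()


class TestCallDe:
    def _results(self, rows):
        return pd.DataFrame(rows, index=[f"G{i}" for i in range(len(rows))],
                            columns=["lfc", "p_adj"])

    def test_signed_thresholds(self):
        res = self._results([(1.2, 0.04), (-1.2, 0.04), (0.9, 0.04),
                             (1.2, 0.06)])
        sets = de.call_de(res)
        assert list(sets["up"]) == ["G0"]
        assert list(sets["down"]) == ["G1"]

    def test_stricter_lfc_cutoff(self):
        res = self._results([(1.2, 0.01), (1.7, 0.01)])
        sets = de.call_de(res, min_abs_lfc=1.5)
        assert list(sets["up"]) == ["G1"]

    def test_bh_single_test_identity_and_step_up(self):
        from statsmodels.stats.multitest import multipletests
        assert multipletests([0.04], method="fdr_bh")[1][0] == pytest.approx(0.04)
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])


class TestDeOverlap:
    def test_identical_and_disjoint(self):
        out = de.de_overlap({"a": {1, 2, 3}, "b": {1, 2, 3}})
        assert out.loc["a&b", "n"] == 3
        out2 = de.de_overlap({"a": {1, 2}, "b": {3, 4}})
        assert out2.loc["a&b", "n"] == 0

    def test_three_sets_match_exhaustive_enumeration(self, rng):
        universe = list(range(10))
        sets = {name: set(rng.choice(universe, size=rng.integers(2, 8),
                                     replace=False).tolist())
                for name in "abc"}
        out = de.de_overlap(sets)
        for _, row in out.iterrows():
            inside = row.name.split("&")
            outside = [n for n in sets if n not in inside]
            expected = sum(
                1 for x in universe
                if all(x in sets[n] for n in inside)
                and not any(x in sets[n] for n in outside))
            assert row["n"] == expected

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            de.de_overlap({"a": {1}})
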