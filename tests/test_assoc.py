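"""Two-stage multilocus scan: screening, stepwise selection, effects,
contribution accounting."""

import numpy as np
import pandas as pd
import pytest

from shadenet import assoc, gasm, pheno, simdata
from shadenet.errors import ValidationError
from shadenet.gasm import GASM, GASMSet


def _marker(gene_id, codes, chrom="chr01", pos=0, n_alleles=2):
    codes = np.asarray(codes, dtype=np.int16)
    return GASM(
        gene_id=gene_id, chrom=chrom, bp_start=pos,
        site_ids=[], alleles=[str(a) for a in range(n_alleles)], codes=codes,
    )


def _biparental_set(code_rows, line_ids=None):
    n = len(code_rows[0])
    line_ids = line_ids or [f"L{i}" for i in range(n)]
    markers = [
        _marker(f"g{j}", row, pos=j * 1000) for j, row in enumerate(code_rows)
    ]
    return GASMSet(gasms=markers, line_ids=line_ids)


class TestEigenCovariates:
    def test_identical_lines_get_identical_rows(self):
        ms = _biparental_set([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0]])
        ev = assoc.eigen_covariates(ms, k=2)
        assert np.allclose(ev[0], ev[1])
        assert np.allclose(ev[2], ev[3])

    def test_clonal_groups_split_on_first_axis(self):
        # two clonal groups of unequal size: block-structured similarity,
        # top eigenvector constant within groups and distinct between them
        rows = [[0] * 6 + [1] * 4 for _ in range(10)]
        ms = _biparental_set(rows)
        ev = assoc.eigen_covariates(ms, k=1)
        first = ev[:, 0]
        assert np.ptp(first[:6]) < 1e-9 and np.ptp(first[6:]) < 1e-9
        assert abs(first[0] - first[6]) > 0.1

    def test_k_zero_and_k_too_large(self):
        ms = _biparental_set([[0, 1, 0, 1]])
        assert assoc.eigen_covariates(ms, k=0).shape == (4, 0)
        with pytest.raises(ValidationError):
            assoc.eigen_covariates(ms, k=4)


class TestStage1:
    def test_monomorphic_locus_skipped(self):
        ms = _biparental_set([[0, 0, 0, 0, 0, 0], [0, 1, 0, 1, 0, 1]])
        y = pd.Series([1.0, 2.0, 1.1, 2.1, 0.9, 1.9], index=ms.line_ids)
        pre = assoc.stage1_preselect(ms, y)
        assert pre.loc[pre["gene_id"] == "g0", "reason"].iloc[0] == "monomorphic"
        assert bool(pre.loc[pre["gene_id"] == "g1", "kept"].iloc[0])

    def test_strong_qtl_always_screened_in(self, gwas_population):
        pop = gwas_population
        markers = GASMSet.from_rils(pop["rils"])
        strong = [g for g, v in pop["qtl_r2"].items() if v >= 0.08]
        hits = 0
        for s in range(10):
            phen = simdata.simulate_phenotypes(pop["rils"], pop["arch"], seed=500 + s)
            y = phen.plots.groupby(["line", "env"], as_index=False)["value"].mean()
            pre = assoc.stage1_preselect(markers, y)
            kept = set(pre.loc[pre["kept"], "gene_id"])
            hits += all(g in kept for g in strong)
        assert hits == 10

    def test_null_trait_type_one_rate(self):
        # independent-ish loci: one gene per chromosome
        gmap = simdata.make_map(400, 1, 50.0, 1, seed=61)
        rils = simdata.simulate_rils(gmap, 200, 6, seed=62)
        markers = GASMSet.from_rils(rils)
        rng = np.random.default_rng(63)
        y = pd.Series(rng.normal(size=200), index=rils.line_ids)
        pre = assoc.stage1_preselect(markers, y)
        frac = pre["kept"].mean()
        se = np.sqrt(0.05 * 0.95 / 400)
        assert abs(frac - 0.05) < 4 * se


class TestStage2:
    def test_cap_zero_gives_empty_model(self, gwas_population):
        pop = gwas_population
        markers = GASMSet.from_rils(pop["rils"])
        phen = simdata.simulate_phenotypes(pop["rils"], pop["arch"], seed=42)
        y = phen.plots.groupby(["line", "env"], as_index=False)["value"].mean()
        fit = assoc.stage2_stepwise(y, markers, h2_cap=0.0, m_total=len(markers))
        assert fit.n_selected == 0

    def test_selected_subset_of_preselected_and_cap_respected(self, gwas_population):
        pop = gwas_population
        markers = GASMSet.from_rils(pop["rils"])
        phen = simdata.simulate_phenotypes(pop["rils"], pop["arch"], seed=43)
        y = phen.plots.groupby(["line", "env"], as_index=False)["value"].mean()
        pre = assoc.stage1_preselect(markers, y)
        cap = 0.85
        fit = assoc.stage2_stepwise(y, markers, preselection=pre, h2_cap=cap, m_total=len(markers))
        kept = set(pre.loc[pre["kept"], "gene_id"])
        assert set(fit.gene_order) <= kept
        assert fit.locus_r2 <= cap + 1e-9

    def test_single_qtl_recovered(self):
        gmap = simdata.make_map(5, 6, 120.0, 1, seed=71)
        rils = simdata.simulate_rils(gmap, 250, 6, seed=72)
        markers = GASMSet.from_rils(rils)
        qtl_gene = gmap.loci[8].gene_id
        arch = simdata.TraitArchitecture(
            qtl=[simdata.QTLEffect(qtl_gene, np.sqrt(0.5), np.zeros(3))],
            mu=1.6, h2_main=0.5, h2_gei=0.0, n_env=3, n_rep=3,
        )
        hits = 0
        for s in range(20):
            phen = simdata.simulate_phenotypes(rils, arch, seed=700 + s)
            y = phen.plots.groupby("line")["value"].mean()
            pre = assoc.stage1_preselect(markers, y)
            fit = assoc.stage2_stepwise(y, markers, preselection=pre, h2_cap=0.8, m_total=len(markers))
            hits += fit.gene_order == [qtl_gene]
        assert hits >= 19

    def test_orthogonal_design_order_invariant(self):
        # 3 mutually orthogonal +-1 loci over 8 lines (full factorial)
        rows = []
        for bit in range(3):
            rows.append([(i >> bit) & 1 for i in range(8)])
        rows = [np.repeat(row, 8) for row in rows]  # 64 lines for residual df
        ms = _biparental_set([r.tolist() for r in rows])
        x = [np.where(np.array(r) == 0, 1.0, -1.0) for r in rows]
        rng = np.random.default_rng(5)
        y_vals = 1.0 + 0.5 * x[0] + 0.3 * x[1] + 0.2 * x[2] + rng.normal(0, 0.05, 64)
        y = pd.Series(y_vals, index=ms.line_ids)
        fit = assoc.stage2_stepwise(y, ms, h2_cap=1.0, m_total=3)
        table = assoc.r2_table(fit).set_index("gene_id")
        # sequential contributions equal marginal R2 on an orthogonal design
        sst = ((y_vals - y_vals.mean()) ** 2).sum()
        for j in range(3):
            marginal = 100 * (x[j] @ (y_vals - y_vals.mean())) ** 2 / (64 * sst)
            assert table.loc[f"g{j}", "r2_main_pct"] == pytest.approx(marginal, rel=1e-6)
        # reversing genome order leaves the selected set unchanged
        ms_rev = GASMSet(gasms=list(reversed(ms.gasms)), line_ids=ms.line_ids)
        fit_rev = assoc.stage2_stepwise(y, ms_rev, h2_cap=1.0, m_total=3)
        assert set(fit_rev.gene_order) == set(fit.gene_order)

    def test_gei_term_requires_main_and_shields_it(self):
        gmap = simdata.make_map(3, 5, 120.0, 1, seed=81)
        rils = simdata.simulate_rils(gmap, 250, 6, seed=82)
        markers = GASMSet.from_rils(rils)
        gene = gmap.loci[4].gene_id
        gei = np.array([0.3, -0.1, -0.2])
        arch = simdata.TraitArchitecture(
            qtl=[simdata.QTLEffect(gene, 0.25, gei)],
            mu=1.6, h2_main=0.3, h2_gei=0.3, n_env=3, n_rep=3,
        )
        phen = simdata.simulate_phenotypes(rils, arch, seed=83)
        y = phen.plots.groupby(["line", "env"], as_index=False)["value"].mean()
        fit = assoc.stage2_stepwise(y, markers, h2_cap=0.9, gei=True, m_total=len(markers))
        kinds = dict((g, k) for g, k in fit.terms)
        assert kinds.get(gene) is not None
        for g, kind in fit.terms:
            if kind == "gei":
                assert (g, "main") in fit.terms


@pytest.fixture(scope="module")
def planted_fit(gwas_population):
    pop = gwas_population
    markers = GASMSet.from_rils(pop["rils"])
    phen = simdata.simulate_phenotypes(pop["rils"], pop["arch"], seed=90)
    y = phen.plots.groupby("line")["value"].mean()
    pre = assoc.stage1_preselect(markers, y)
    fit = assoc.stage2_stepwise(y, markers, preselection=pre, h2_cap=0.9, m_total=len(markers))
    return pop, fit, y


class TestEffectsAndContributions:
    def test_allele_effects_sum_to_zero(self, planted_fit):
        _, fit, _ = planted_fit
        table = assoc.allele_effects(fit)
        main = table[table["term"] == "main"]
        sums = main.groupby("gene_id")["effect"].sum()
        assert np.allclose(sums, 0.0, atol=1e-9)

    def test_planted_effects_recovered(self, planted_fit):
        pop, fit, _ = planted_fit
        for gene, r2 in pop["qtl_r2"].items():
            if r2 < 0.08 or gene not in fit.allele_effects:
                continue
            a_hat = fit.allele_effects[gene][0]  # parent-1 allele effect
            a_true = np.sqrt(r2)
            assert a_hat == pytest.approx(a_true, abs=0.06)

    def test_r2_decomposition_identity(self, planted_fit):
        _, fit, _ = planted_fit
        table = assoc.r2_table(fit)
        assert table["r2_main_pct"].sum() == pytest.approx(100 * fit.locus_r2, abs=1e-6)
        # marker SS + residual SS = total SS (intercept-only base model)
        assert fit.locus_r2 + fit.rss / fit.sst == pytest.approx(1.0, abs=1e-9)

    def test_sequential_close_to_partial_on_ril_panel(self, planted_fit):
        _, fit, _ = planted_fit
        diag = assoc.sequential_vs_partial_r2(fit)
        # unlinked loci: attributions agree up to finite-sample correlation,
        # which the earliest entries absorb into their sequential share
        assert np.allclose(diag["sequential_r2_pct"], diag["partial_r2_pct"], atol=10.0)
        assert diag["sequential_r2_pct"].sum() == pytest.approx(100 * fit.locus_r2, abs=1e-6)


class TestAccounting:
    def test_lc_boundary_is_inclusive(self):
        assert assoc.lc_class(1.5) == "LC"
        assert assoc.lc_class(1.4999) == "SC"

    @pytest.mark.parametrize(
        "h2,mapped,expected",
        [(67.17, 57.44, 9.73), (98.88, 96.42, 2.46)],
    )
    def test_polygene_remainder(self, h2, mapped, expected):
        table = pd.DataFrame(
            {"gene_id": ["a", "b"], "r2_main_pct": [1.6, mapped - 1.6],
             "r2_gei_pct": [0.0, 0.0], "class": ["LC", "SC"]}
        )
        acc = assoc.contribution_summary(table, h2_main_pct=h2)
        assert acc.polygene_main_pct == pytest.approx(expected, abs=1e-9)
        assert acc.mapped_main_pct == pytest.approx(mapped)

    def test_negative_remainder_rejected(self):
        table = pd.DataFrame(
            {"gene_id": ["a"], "r2_main_pct": [60.0], "r2_gei_pct": [0.0], "class": ["LC"]}
        )
        with pytest.raises(ValidationError):
            assoc.contribution_summary(table, h2_main_pct=50.0)

    def test_two_trait_union(self):
        assert assoc.union_count(99, 119, 7) == 211
        assert assoc.union_count(3, 4, 0) == 7
        with pytest.raises(ValidationError):
            assoc.union_count(3, 4, 5)
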