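"""Generator correctness: map layout, meiosis genetics, heritability
calibration, expression truth structure."""

import numpy as np
import pandas as pd
import pytest

from shadenet import deg, pheno, simdata
from shadenet.errors import ConfigError
from shadenet.simdata import HET, P1, P2, haldane, ril_recombination_fraction


class TestMakeMap:
    @pytest.mark.parametrize(
        "n_chrom,genes,length,snps,expect_loci",
        [(1, 5, 100.0, 3, 5), (20, 10, 120.0, 2, 200)],
    )
    def test_dimensions_and_ordering(self, n_chrom, genes, length, snps, expect_loci):
        gmap = simdata.make_map(n_chrom, genes, length, snps, seed=1)
        assert gmap.n_loci == expect_loci
        assert len(gmap.chromosomes) == n_chrom
        for chrom in gmap.chromosomes:
            pos = [l.pos_cM for l in gmap.loci_for(chrom.chrom_id)]
            assert all(0 <= p <= length for p in pos)
            assert pos == sorted(pos) and len(set(pos)) == len(pos)

    def test_deterministic_for_fixed_seed(self):
        a = simdata.make_map(3, 7, 80.0, (1, 4), seed=9)
        b = simdata.make_map(3, 7, 80.0, (1, 4), seed=9)
        assert a.loci == b.loci and a.chromosomes == b.chromosomes

    @pytest.mark.parametrize("bad", [dict(n_chrom=0, genes_per_chrom=5),
                                     dict(n_chrom=1, genes_per_chrom=0),
                                     dict(n_chrom=1, genes_per_chrom=5, chrom_length_cM=-1)])
    def test_invalid_configuration(self, bad):
        kwargs = dict(n_chrom=1, genes_per_chrom=5, chrom_length_cM=100.0)
        kwargs.update(bad)
        with pytest.raises(ConfigError):
            simdata.make_map(**kwargs)


def _two_locus_map(distance_cM: float) -> simdata.GeneticMap:
    return simdata.GeneticMap(
        [simdata.Chromosome("chr01", max(distance_cM + 20.0, 30.0))],
        [
            simdata.Locus("gA", "chr01", 10.0, 100, 200, 1),
            simdata.Locus("gB", "chr01", 10.0 + distance_cM, 10_000, 10_100, 1),
        ],
    )


def _recombinant_fraction(rils: simdata.RILGenotypes) -> float:
    src = rils.sources
    fixed = np.all((src == P1) | (src == P2), axis=1)
    s = src[fixed]
    return float((s[:, 0] != s[:, 1]).mean())


class TestSimulateRILs:
    def test_tightly_linked_loci_never_recombine(self):
        gmap = _two_locus_map(1e-9)
        rils = simdata.simulate_rils(gmap, 2000, 20, seed=3)
        assert _recombinant_fraction(rils) == 0.0

    def test_recombinant_fraction_matches_ril_formula(self):
        # single-seed-descent limit R = 2r/(1+2r) with Haldane r at 10 cM
        gmap = _two_locus_map(10.0)
        rils = simdata.simulate_rils(gmap, 2000, 20, seed=4)
        r = haldane(10.0)
        R = ril_recombination_fraction(r)
        se = np.sqrt(R * (1 - R) / 2000)
        assert abs(_recombinant_fraction(rils) - R) < 3 * se

    def test_parental_allele_frequencies_balanced(self):
        gmap = _two_locus_map(10.0)
        rils = simdata.simulate_rils(gmap, 2000, 20, seed=5)
        freq = (rils.sources == P1).mean(axis=0)
        se = np.sqrt(0.25 / 2000)
        assert np.all(np.abs(freq - 0.5) < 4 * se)

    def test_heterozygosity_decays_by_half_per_selfing(self):
        gmap = simdata.make_map(1, 4, 100.0, 1, seed=6)
        for gens in (2, 4):
            rils = simdata.simulate_rils(gmap, 4000, gens, seed=7)
            het = (rils.sources == HET).mean()
            expected = 0.5**gens
            se = np.sqrt(expected * (1 - expected) / (4000 * 4))
            assert abs(het - expected) < 4 * se

    def test_snp_alleles_follow_locus_source(self, small_rils):
        for j, site in enumerate(small_rils.snp_sites.itertuples(index=False)):
            src = small_rils.sources[:, site.locus]
            col = small_rils.snp_alleles[:, j]
            fixed = (src == P1) | (src == P2)
            assert np.array_equal(col[fixed], src[fixed])
            assert np.all(col[~fixed] == simdata.MISSING)

    def test_deterministic_and_requires_loci(self, small_map):
        a = simdata.simulate_rils(small_map, 30, 6, seed=8)
        b = simdata.simulate_rils(small_map, 30, 6, seed=8)
        assert np.array_equal(a.sources, b.sources)
        assert np.array_equal(a.snp_alleles, b.snp_alleles)
        with pytest.raises(ConfigError):
            simdata.simulate_rils(simdata.GeneticMap([], []), 10, 6)


class TestArchitecture:
    def test_zero_gei_scale_gives_zero_effects(self, small_map):
        arch = simdata.assign_architecture(small_map, 5, gei_sd=0.0, seed=1)
        assert all(np.all(q.gei == 0) for q in arch.qtl)

    def test_no_qtl_trait_is_pure_noise(self, small_map, small_rils):
        arch = simdata.assign_architecture(small_map, 0, seed=2)
        phen = simdata.simulate_phenotypes(small_rils, arch, seed=3)
        assert phen.truth["h2_main"] == 0.0
        assert float(phen.truth["genetic_values"].abs().sum()) == 0.0

    def test_reproducible_and_bounded(self, small_map):
        a = simdata.assign_architecture(small_map, 6, seed=5)
        b = simdata.assign_architecture(small_map, 6, seed=5)
        assert [(q.gene_id, q.a) for q in a.qtl] == [(q.gene_id, q.a) for q in b.qtl]
        with pytest.raises(ConfigError):
            simdata.assign_architecture(small_map, small_map.n_loci + 1)
        with pytest.raises(ConfigError):
            simdata.TraitArchitecture([], 1.6, 0.7, 0.4, 3, 3)  # targets sum >= 1


class TestSimulatePhenotypes:
    def test_noiseless_limit_recovers_full_heritability(self, small_map, small_rils):
        arch = simdata.assign_architecture(
            small_map, 5, gei_sd=0.0, h2_main=1 - 1e-9, h2_gei=0.0, seed=4
        )
        phen = simdata.simulate_phenotypes(small_rils, arch, seed=5, env_main_sd=0.0)
        vc = pheno.anova_components(phen.plots)
        h2 = pheno.heritability(vc)
        assert vc.sigma2_eps < 1e-8
        assert h2["h2_total"] > 0.9999

    def test_heritability_calibration_in_expectation(self):
        # the generating model's own partition is recovered on average
        gmap = simdata.make_map(5, 8, 120.0, 1, seed=31)
        rils = simdata.simulate_rils(gmap, 246, 6, seed=32)
        arch = simdata.assign_architecture(
            gmap, 10, h2_main=0.67, h2_gei=0.18, n_env=3, n_rep=3, seed=33
        )
        h2m, h2g = [], []
        for s in range(200):
            phen = simdata.simulate_phenotypes(rils, arch, seed=1000 + s)
            h = pheno.heritability(pheno.anova_components(phen.plots))
            h2m.append(h["h2_main"])
            h2g.append(h["h2_gei"])
        assert abs(np.mean(h2m) - 0.67) < 0.03
        assert abs(np.mean(h2g) - 0.18) < 0.03

    def test_raw_mode_reconstruction_is_exact(self, small_map, small_rils):
        arch = simdata.assign_architecture(small_map, 4, seed=6)
        phen = simdata.simulate_phenotypes(small_rils, arch, mode="raw", seed=7)
        sti = pheno.sti_table(phen.plots)
        latent = phen.truth["latent"].rename(columns={"value": "latent"})
        merged = sti.merge(latent, on=["line", "env", "rep"])
        assert len(merged) == len(latent)
        assert np.allclose(merged["value"], merged["latent"], atol=1e-9)

    def test_raw_mode_rejects_bad_node_baseline(self, small_map, small_rils):
        arch = simdata.assign_architecture(small_map, 4, seed=6)
        with pytest.raises(ConfigError):
            simdata.simulate_phenotypes(small_rils, arch, mode="raw", seed=7, nn_range=(0, 3))

    def test_cell_records_reproduce_latent_rcl(self):
        latent = pd.DataFrame(
            {"line": ["L1"] * 3 + ["L2"] * 3, "rep": [1, 2, 3] * 2,
             "value": [1.1, 0.9, 1.3, 0.7, 1.0, 1.2]}
        )
        cells = simdata.build_cell_records(latent, seed=8)
        table = pheno.rcl_table(cells, n_sample=None)
        merged = table.merge(latent, on=["line", "rep"], suffixes=("_obs", "_latent"))
        assert np.allclose(merged["value_obs"], merged["value_latent"], atol=1e-9)


class TestSimulateExpression:
    def test_zero_de_fraction_plants_nothing(self):
        expr = simdata.simulate_expression(n_genes=200, de_fraction=0.0, seed=1)
        assert not expr.truth["is_de"].any()
        assert (expr.counts.to_numpy() >= 0).all()

    def test_replicate_layout_complete(self):
        expr = simdata.simulate_expression(n_genes=50, n_rep=3, seed=2)
        counts = expr.samples.groupby(["genotype", "condition"]).size()
        assert (counts == 3).all() and len(counts) == 4

    def test_strong_planted_signal_is_recovered(self):
        expr = simdata.simulate_expression(
            n_genes=400, de_fraction=0.25, lfc_range=(3.0, 3.0),
            dispersion=0.01, mean_range=(500.0, 2000.0), seed=3,
        )
        fpkm_df = deg.fpkm(expr.counts, expr.lengths)
        calls = deg.call_degs(fpkm_df, expr.samples, ("G", "S"), ("G", "CK"))
        truth = expr.truth[expr.truth["contrast"] == "G_S_vs_CK"]
        planted = set(truth.loc[truth["is_de"], "gene"])
        recovered = planted & set(calls["gene_id"])
        assert len(recovered) >= 0.95 * len(planted)

    def test_library_size_scaling_invariance(self):
        expr = simdata.simulate_expression(n_genes=100, seed=4)
        f1 = deg.fpkm(expr.counts, expr.lengths)
        doubled = expr.counts.copy()
        doubled.iloc[:, 0] = doubled.iloc[:, 0] * 2
        f2 = deg.fpkm(doubled, expr.lengths)
        assert np.allclose(f1.iloc[:, 0], f2.iloc[:, 0])

    def test_invalid_parameters(self):
        with pytest.raises(ConfigError):
            simdata.simulate_expression(n_genes=10, dispersion=-0.1)
        with pytest.raises(ConfigError):
            simdata.simulate_expression(n_genes=10, de_fraction=1.5)
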