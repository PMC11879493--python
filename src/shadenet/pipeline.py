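"""End-to-end orchestration: simulate -> indicators -> heritability ->
marker assembly -> association -> cross planning -> expression -> network.

`run_pipeline` executes the stages in dependency order from one structured
config with a single global seed (fanned out to per-stage seeds through a
`numpy.random.SeedSequence` spawn, so stages are individually reproducible)
and returns a report whose accounting identities (pair counts, gene union,
Venn totals, polygene remainder) are verified before it is emitted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, crossplan, deg, gasm, netstats, pheno, simdata
from .errors import ConfigError, ValidationError


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults."""

    seed: int = 1
    # population / genome
    n_lines: int = 246
    n_chrom: int = 10
    genes_per_chrom: int = 12
    chrom_length_cM: float = 120.0
    snps_per_gene: tuple[int, int] = (1, 4)
    n_selfing_gens: int = 6
    # trait architecture
    n_qtl: int = 10
    h2_main: float = 0.6717
    h2_gei: float = 0.1802
    n_env: int = 3
    n_rep: int = 3
    mu: float = 1.6
    effect_sd: float = 0.06
    gei_sd: float = 0.04
    # association scan
    alpha1: float = 0.05
    alpha2: float = 0.05
    h2_cap: float | None = None  # None: use the ANOVA-estimated total h2
    eigen_k: int = 0
    gei: bool = True
    lc_threshold: float = 1.5
    # cross planning
    direction: str = "smaller_better"
    linkage_n_progeny: int = 300
    linkage_generations: int = 5
    # expression
    n_expr_genes: int = 3000
    de_fraction: float = 0.15
    lfc_range: tuple[float, float] = (1.0, 3.0)
    dispersion: float = 0.05
    expr_mean_range: tuple[float, float] = (20.0, 2000.0)
    expr_n_rep: int = 3
    p_max: float = 0.05
    lfc_min: float = 0.807
    pseudocount: float = 1.0
    # network
    min_score: float = 0.18
    hub_threshold: int = 10
    chunk_size: int = 2000
    top_k: int = 5
    ppi_mean_attach: int = 2
    # output
    outdir: str | None = None

    def validate(self):
        checks = [
            (0 < self.alpha1 <= 1, "alpha1"),
            (0 <= self.alpha2 <= 1, "alpha2"),
            (0 <= self.lfc_min, "lfc_min"),
            (0 < self.p_max <= 1, "p_max"),
            (0 <= self.min_score <= 1, "min_score"),
            (self.hub_threshold >= 0, "hub_threshold"),
            (self.chunk_size >= 1, "chunk_size"),
            (self.lc_threshold >= 0, "lc_threshold"),
        ]
        for ok, name in checks:
            if not ok:
                raise ConfigError(f"{name} outside its documented domain")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a seeded synthetic dataset and return the report.

    The report is a plain nested dict (JSON-serializable except for the
    attached result objects under 'objects') whose 'checks' section records
    the verified accounting identities. Identical config and seed give an
    identical report.
    """
    config.validate()
    seeds = _stage_seeds(config.seed)
    report: dict = {"config": {k: v for k, v in dataclasses.asdict(config).items()}, "stages": {}, "checks": {}}
    objects: dict = {}

    # --- simulate population and phenotypes -------------------------------
    gmap = simdata.make_map(
        config.n_chrom, config.genes_per_chrom, config.chrom_length_cM,
        config.snps_per_gene, seed=seeds[0],
    )
    rils = simdata.simulate_rils(gmap, config.n_lines, config.n_selfing_gens, seed=seeds[1])
    arch = simdata.assign_architecture(
        gmap, config.n_qtl, effect_sd=config.effect_sd, gei_sd=config.gei_sd,
        h2_main=config.h2_main, h2_gei=config.h2_gei,
        n_env=config.n_env, n_rep=config.n_rep, mu=config.mu, seed=seeds[2],
    )
    phen = simdata.simulate_phenotypes(rils, arch, mode="indicator", seed=seeds[3])
    report["stages"]["simulate"] = {
        "n_lines": rils.n_lines,
        "n_loci": gmap.n_loci,
        "n_snps": int(rils.snp_alleles.shape[1]),
        "generation": rils.generation,
        "n_qtl": len(arch.qtl),
    }

    # --- heritability ------------------------------------------------------
    vc = pheno.anova_components(phen.plots)
    h2 = pheno.heritability(vc)
    report["stages"]["pheno"] = {
        "sigma2_g": vc.sigma2_g,
        "sigma2_ge": vc.sigma2_ge,
        "sigma2_eps": vc.sigma2_eps,
        "h2_total_pct": 100 * h2["h2_total"],
        "h2_main_pct": 100 * h2["h2_main"],
        "h2_gei_pct": 100 * h2["h2_gei"],
        "gcv_pct": 100 * pheno.gcv(vc.sigma2_g**0.5, vc.mu),
    }

    # --- marker assembly ---------------------------------------------------
    snps = gasm.SNPTable.from_rils(rils)
    genes = gasm.GeneAnnotation.from_map(gmap)
    markers = gasm.assemble_gasms(snps, genes)
    report["stages"]["gasm"] = gasm.gasm_summary(markers)

    # --- association -------------------------------------------------------
    y = phen.plots.groupby(["line", "env"], as_index=False)["value"].mean()
    cov = assoc.eigen_covariates(markers, k=config.eigen_k) if config.eigen_k else None
    pre = assoc.stage1_preselect(markers, y, covariates=cov, alpha1=config.alpha1)
    cap = config.h2_cap if config.h2_cap is not None else h2["h2_total"]
    fit = assoc.stage2_stepwise(
        y, markers, preselection=pre, covariates=cov,
        alpha2=config.alpha2, h2_cap=cap, gei=config.gei, m_total=len(markers),
    )
    table = assoc.r2_table(fit, lc_threshold=config.lc_threshold)
    accounting = assoc.contribution_summary(
        table, h2_main_pct=100 * h2["h2_main"], h2_gei_pct=100 * h2["h2_gei"], tol=1.0
    ) if len(table) else None
    report["stages"]["assoc"] = {
        "n_preselected": int(pre["kept"].sum()),
        "n_selected": fit.n_selected,
        "locus_r2_pct": 100 * fit.locus_r2,
        "h2_cap_pct": 100 * cap,
        "n_lc": accounting.n_lc if accounting else 0,
        "n_sc": accounting.n_sc if accounting else 0,
        "mapped_main_pct": accounting.mapped_main_pct if accounting else 0.0,
        "polygene_main_pct": accounting.polygene_main_pct if accounting else 100 * h2["h2_main"],
    }

    # --- cross planning ----------------------------------------------------
    if fit.n_selected == 0:
        report["stages"]["crossplan"] = {"skipped": "no markers selected"}
        summary = None
    else:
        matrix = crossplan.build_matrix(fit, markers, gmap=gmap, direction=config.direction)
        summary = crossplan.summarize_pairs(matrix, model="independent")
        best_pair = summary.values.loc[
            summary.values["value"].idxmin() if config.direction == "smaller_better"
            else summary.values["value"].idxmax()
        ]
        link = crossplan.potential_linkage(
            matrix, gmap, best_pair["i"], best_pair["j"],
            n_progeny=config.linkage_n_progeny, generations=config.linkage_generations,
            seed=seeds[4],
        )
        report["stages"]["crossplan"] = {
            "n_pairs": summary.n_pairs,
            "p10_favorable_independent": summary.p10_favorable,
            "best_independent": summary.best,
            "best_pair": [best_pair["i"], best_pair["j"]],
            "best_pair_linkage": link.value,
        }
        objects["matrix"] = matrix

    # --- expression --------------------------------------------------------
    expr_gene_ids = list(gmap.gene_ids) + [
        f"Gene{i + 1:05d}" for i in range(config.n_expr_genes - gmap.n_loci)
    ]
    expr = simdata.simulate_expression(
        n_genes=config.n_expr_genes, de_fraction=config.de_fraction,
        lfc_range=config.lfc_range, dispersion=config.dispersion,
        mean_range=config.expr_mean_range, n_rep=config.expr_n_rep,
        seed=seeds[5], gene_ids=expr_gene_ids,
    )
    fpkm_df = deg.fpkm(expr.counts, expr.lengths)
    calls_g = deg.call_degs(fpkm_df, expr.samples, ("G", "S"), ("G", "CK"),
                            p_max=config.p_max, lfc_min=config.lfc_min, pseudocount=config.pseudocount)
    calls_z = deg.call_degs(fpkm_df, expr.samples, ("Z", "S"), ("Z", "CK"),
                            p_max=config.p_max, lfc_min=config.lfc_min, pseudocount=config.pseudocount)
    venn = deg.venn_partition(calls_g, calls_z)
    overlap = deg.intersect_gwas(calls_g, fit.gene_order)
    report["stages"]["deg"] = {
        "G": deg.up_down_totals(calls_g),
        "Z": deg.up_down_totals(calls_z),
        "venn": {
            "unique_a": venn.unique_a, "unique_b": venn.unique_b,
            "shared": venn.shared, "shared_same_trend": venn.shared_same_trend,
            "shared_opposite_trend": venn.shared_opposite_trend,
            "union_total": venn.union_total,
        },
        "gwas_overlap": int(overlap["gene_id"].nunique()) if len(overlap) else 0,
    }

    # --- network -----------------------------------------------------------
    deg_union = sorted(set(calls_g["gene_id"]) | set(calls_z["gene_id"]))
    if len(deg_union) > config.ppi_mean_attach + 1:
        raw_edges = simdata.simulate_ppi_edges(deg_union, m=config.ppi_mean_attach, seed=seeds[6])
        edges = netstats.filter_edges(raw_edges, min_score=config.min_score)
        graph = netstats.build_graph(edges)
        hub_table = netstats.hubs(graph, hub_threshold=config.hub_threshold)
        groups = netstats.chunk(deg_union, max_size=config.chunk_size, seed=seeds[7])
        group_hubs = {
            gid: hub_table[hub_table["node"].isin(groups.index[groups == gid])]
            for gid in sorted(groups.unique())
        }
        top, meta = netstats.top_hubs_meta(group_hubs, edges, k=config.top_k)
        sizes = netstats.component_sizes(graph)
        report["stages"]["netstats"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_components": len(sizes),
            "largest_component": sizes[0] if sizes else 0,
            "n_key_hubs": int(hub_table["is_key_hub"].sum()),
            "n_groups": int(groups.nunique()),
            "n_meta_hubs": int(len(top)),
            "meta_edges": meta.number_of_edges(),
        }
    else:
        report["stages"]["netstats"] = {"skipped": "too few DEGs for a network"}

    # --- accounting identity checks ---------------------------------------
    checks = {}
    n = rils.n_lines
    if summary is not None:
        checks["pair_count"] = summary.n_pairs == n * (n - 1) // 2
    checks["venn_union"] = venn.union_total == venn.unique_a + venn.unique_b + venn.shared
    checks["venn_trend_split"] = venn.shared == venn.shared_same_trend + venn.shared_opposite_trend
    checks["contrast_totals"] = (
        venn.total_a == len(calls_g) and venn.total_b == len(calls_z)
    )
    if accounting is not None:
        checks["polygene_nonneg"] = accounting.polygene_main_pct >= -1.0
        checks["cap_respected"] = 100 * fit.locus_r2 <= 100 * cap + 1e-9
    if not all(checks.values()):
        raise ValidationError(f"accounting identity violated: {checks}")
    report["checks"] = checks

    objects.update({"gmap": gmap, "rils": rils, "arch": arch, "phenotypes": phen,
                    "markers": markers, "fit": fit, "r2_table": table,
                    "expr": expr, "calls_g": calls_g, "calls_z": calls_z, "venn": venn})
    report["objects"] = objects

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in report.items() if k != "objects"}
        with open(out / "run_report.json", "w") as fh:
            json.dump(serializable, fh, indent=1, default=float)
    return report
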