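"""Plain-text writers for the simulated data dialects.

Coordinate conventions: VCF and GFF3 are 1-based closed, BED is 0-based
half-open; internal locus coordinates are 0-based half-open; SNP positions
are stored 1-based (VCF convention).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import simdata
from .simdata import GeneticMap, RILGenotypes, SimExpression, TraitArchitecture


def write_genotype_tsv(rils: RILGenotypes, path: str | Path) -> None:
    """Lines x SNP sites, codes 0/1/NA (residual heterozygotes are NA)."""
    cols = {"line": rils.line_ids}
    for j, site in enumerate(rils.snp_sites.itertuples(index=False)):
        col = rils.snp_alleles[:, j]
        cols[site.id] = [str(int(v)) if v >= 0 else "NA" for v in col]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_vcf(rils: RILGenotypes, path: str | Path) -> None:
    """Minimal VCF v4.2, GT-only; P1 allele is REF (A), P2 allele ALT (T);
    residual heterozygotes are written 0/1."""
    sites = rils.snp_sites
    contigs = {}
    for rec in sites.itertuples(index=False):
        contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), rec.pos + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=shadenet-simdata\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(rils.line_ids) + "\n")
        for j, rec in enumerate(sites.itertuples(index=False)):
            locus_idx = rec.locus
            src = rils.sources[:, locus_idx]
            col = rils.snp_alleles[:, j]
            gts = []
            for i in range(rils.n_lines):
                if col[i] == 0:
                    gts.append("0/0")
                elif col[i] == 1:
                    gts.append("1/1")
                elif src[i] == simdata.HET:
                    gts.append("0/1")
                else:
                    gts.append("./.")
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_bed(gmap: GeneticMap, path: str | Path) -> None:
    """Gene intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for loc in gmap.loci:
            fh.write(f"{loc.chrom_id}\t{loc.bp_start}\t{loc.bp_end}\t{loc.gene_id}\t0\t+\n")


def write_gff3(gmap: GeneticMap, path: str | Path) -> None:
    """Gene features as GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in gmap.loci:
            fh.write(
                f"{loc.chrom_id}\tshadenet\tgene\t{loc.bp_start + 1}\t{loc.bp_end}\t.\t+\t.\tID={loc.gene_id}\n"
            )


def write_map_tsv(gmap: GeneticMap, path: str | Path) -> None:
    gmap.loci_frame().to_csv(path, sep="\t", index=False)


def write_phenotype_csv(plots: pd.DataFrame, path: str | Path) -> None:
    """Long-format plot table (line, env, rep[, condition, PH, NN | value])."""
    plots.to_csv(path, index=False)


def write_cell_csv(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def write_counts_tsv(expr: SimExpression, path: str | Path) -> None:
    expr.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def write_gene_lengths_tsv(expr: SimExpression, path: str | Path) -> None:
    expr.lengths.rename_axis("gene_id").to_csv(path, sep="\t")


def write_sample_sheet_csv(expr: SimExpression, path: str | Path) -> None:
    expr.samples.to_csv(path, index=False)


def write_truth_json(path: str | Path, arch: TraitArchitecture | None = None,
                     expr: SimExpression | None = None) -> None:
    """Generator ground truth: QTL effects and planted DE flags."""
    payload = {}
    if arch is not None:
        payload["qtl"] = [
            {"gene_id": q.gene_id, "a": q.a, "gei": list(map(float, q.gei))} for q in arch.qtl
        ]
        payload["mu"] = arch.mu
        payload["h2_main"] = arch.h2_main
        payload["h2_gei"] = arch.h2_gei
    if expr is not None:
        payload["de"] = expr.truth.to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def read_gene_lengths_tsv(path: str | Path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="gene_id")["length"]


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
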