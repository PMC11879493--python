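"""Gene–allele sequence markers: assemble within-gene SNP haplotypes.

A gene–allele marker concatenates the alleles of every biallelic SNP inside
one annotated gene into a haplotype string per line; the distinct observed
complete haplotypes become the marker's alleles. In a biparental RIL panel
without intra-gene recombination each marker carries exactly two alleles;
recombinant or mutant haplotypes add further alleles.

The module also owns genotype and annotation I/O: VCF (v4.2, GT-based, via
cyvcf2) and coded TSV genotypes, GFF3 (via gffutils) and BED gene intervals.
Internal coordinates are 0-based half-open; VCF positions are 1-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from . import simdata

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class SNPTable:
    """Biallelic SNP sites and a lines x sites allele-code matrix (0/1/-1)."""

    sites: pd.DataFrame  # columns: chrom, pos (1-based), id
    matrix: np.ndarray
    line_ids: list[str]
    n_skipped_multiallelic: int = 0

    def __post_init__(self):
        if self.matrix.shape != (len(self.line_ids), len(self.sites)):
            raise ValidationError("matrix shape does not match sites/lines")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"positions not strictly increasing on {chrom}")
        bad = ~np.isin(self.matrix, (0, 1, MISSING))
        if bad.any():
            raise ValidationError("allele codes must be 0, 1 or missing")

    @classmethod
    def from_rils(cls, rils: simdata.RILGenotypes) -> "SNPTable":
        return cls(
            sites=rils.snp_sites[["chrom", "pos", "id"]].copy(),
            matrix=rils.snp_alleles.copy(),
            line_ids=list(rils.line_ids),
        )


@dataclass
class GeneAnnotation:
    """Gene intervals with 0-based half-open coordinates."""

    records: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self):
        r = self.records
        if r["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in annotation")
        if (r["start"] > r["end"]).any():
            raise ValidationError("gene start must be <= end")

    @classmethod
    def from_map(cls, gmap: simdata.GeneticMap) -> "GeneAnnotation":
        df = gmap.loci_frame().rename(columns={"bp_start": "start", "bp_end": "end"})
        df["strand"] = "+"
        return cls(df[["gene_id", "chrom", "start", "end", "strand"]])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str | None = None) -> SNPTable:
    """Read a genotype matrix from VCF or coded TSV.

    Only biallelic sites are kept; multi-allelic sites are skipped and
    counted. In VCFs, heterozygous and uncalled genotypes both map to
    missing (inbred lines are effectively haploid at fixed sites).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz"} else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ParseError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> SNPTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, cols = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown-by-convention varies; use genotypes
        codes = np.empty(len(line_ids), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0 or a != b:
                codes[i] = MISSING
            else:
                codes[i] = a
        rows.append({"chrom": var.CHROM, "pos": var.POS, "id": var.ID or f"{var.CHROM}_{var.POS}"})
        cols.append(codes)
    if not rows:
        raise ParseError(f"no biallelic sites in {path}")
    sites = pd.DataFrame(rows)
    matrix = np.stack(cols, axis=1)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    matrix = matrix[:, order]
    return SNPTable(sites=sites, matrix=matrix, line_ids=line_ids, n_skipped_multiallelic=skipped)


def _read_tsv(path: Path) -> SNPTable:
    """Coded TSV: first column ``line``, one column per site named
    ``chrom:pos`` or ``chrom_pos``; values 0, 1 or NA."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "line":
        raise ParseError("genotype TSV must start with a 'line' column")
    line_ids = df["line"].tolist()
    site_cols = list(df.columns[1:])
    rows = []
    for name in site_cols:
        sep = ":" if ":" in name else "_"
        try:
            chrom, pos = name.rsplit(sep, 1)
            pos = int(pos)
        except ValueError as exc:
            raise ParseError(f"cannot parse site column {name!r}") from exc
        rows.append({"chrom": chrom, "pos": pos, "id": name.replace(":", "_")})
    sites = pd.DataFrame(rows)
    matrix = np.full((len(line_ids), len(site_cols)), MISSING, dtype=np.int8)
    for j, name in enumerate(site_cols):
        col = df[name]
        for i, v in enumerate(col):
            if isinstance(v, str) and v not in {"NA", "", "."}:
                try:
                    code = int(v)
                except ValueError as exc:
                    raise ParseError(f"bad allele code {v!r} at line {i + 2}") from exc
                if code not in (0, 1):
                    raise ParseError(f"bad allele code {v!r} at line {i + 2}")
                matrix[i, j] = code
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    matrix = matrix[:, order]
    return SNPTable(sites=sites, matrix=matrix, line_ids=line_ids)


def read_annotation(path: str | Path, format: str | None = None) -> GeneAnnotation:
    """Read gene intervals from GFF3 (1-based closed) or BED (0-based
    half-open); both are normalized to 0-based half-open."""
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix in {".gff", ".gff3"} else "bed"
    if format == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
        )
        rows = []
        for feat in db.features_of_type("gene"):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            rows.append(
                {"gene_id": gene_id, "chrom": feat.seqid, "start": feat.start - 1, "end": feat.end, "strand": feat.strand or "+"}
            )
        return GeneAnnotation(pd.DataFrame(rows))
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 4:
            raise ParseError("BED needs chrom, start, end, name columns")
        out = pd.DataFrame(
            {
                "gene_id": df[3],
                "chrom": df[0],
                "start": df[1].astype(int),
                "end": df[2].astype(int),
                "strand": df[5] if df.shape[1] > 5 else "+",
            }
        )
        return GeneAnnotation(out)
    raise ParseError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


@dataclass
class GASM:
    """One multi-allelic gene–allele marker."""

    gene_id: str
    chrom: str
    bp_start: int
    site_ids: list[str]
    alleles: list[str]  # distinct complete haplotype strings, frequency-ordered
    codes: np.ndarray  # per-line allele index, -1 missing

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclass
class GASMSet:
    gasms: list[GASM]
    line_ids: list[str]

    def __len__(self):
        return len(self.gasms)

    def __iter__(self):
        return iter(self.gasms)

    def __getitem__(self, i):
        return self.gasms[i]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.gasms]

    def codes_matrix(self) -> np.ndarray:
        """(n_gasms, n_lines) allele-index matrix, -1 for missing."""
        if not self.gasms:
            return np.zeros((0, len(self.line_ids)), dtype=np.int16)
        return np.stack([g.codes for g in self.gasms], axis=0)

    def by_gene(self, gene_id: str) -> GASM:
        for g in self.gasms:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @classmethod
    def from_rils(cls, rils: simdata.RILGenotypes) -> "GASMSet":
        """Direct biparental markers from simulated haplotype sources
        (parent 1 allele 0, parent 2 allele 1, residual heterozygotes
        missing). Convenient for simulation studies that do not need the
        SNP-level assembly path."""
        gasms = []
        locus_by_gene = {l.gene_id: l for l in []}
        for idx, gene in enumerate(rils.gene_ids):
            src = rils.sources[:, idx]
            codes = np.where(src == simdata.P1, 0, np.where(src == simdata.P2, 1, -1)).astype(np.int16)
            sites = rils.snp_sites[rils.snp_sites["locus"] == idx]
            gasms.append(
                GASM(
                    gene_id=gene,
                    chrom=str(sites["chrom"].iloc[0]),
                    bp_start=int(sites["pos"].min()) - 1,
                    site_ids=sites["id"].tolist(),
                    alleles=["0" * len(sites), "1" * len(sites)],
                    codes=codes,
                )
            )
        return cls(gasms=gasms, line_ids=list(rils.line_ids))


def assemble_gasms(
    snps: SNPTable,
    genes: GeneAnnotation,
    missing_policy: str = "match_or_missing",
    min_lines: int | None = None,
) -> GASMSet:
    """Assemble all SNPs within each gene interval into one multi-allelic
    marker.

    Distinct complete haplotypes (no missing site) become the alleles,
    ordered by descending frequency then lexicographically. A haplotype with
    missing sites is assigned under ``missing_policy``:

    * ``match_or_missing`` (default): assigned only when exactly one observed
      complete haplotype is compatible with its non-missing sites, otherwise
      the line is missing at that marker;
    * ``strict``: any missing site makes the line missing.

    Genes with no SNPs and monomorphic markers are dropped; so are markers
    whose non-missing line count falls below ``min_lines`` (default: 80% of
    lines). Assembly ignores strand: haplotypes read in ascending bp on the
    reference orientation.
    """
    if missing_policy not in {"match_or_missing", "strict"}:
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    n_lines = len(snps.line_ids)
    if min_lines is None:
        min_lines = math.ceil(0.8 * n_lines)

    shared = set(snps.sites["chrom"]) & set(genes.records["chrom"])
    if not shared:
        logger.warning("no chromosome shared between SNPs and annotation; empty marker set")
        return GASMSet(gasms=[], line_ids=list(snps.line_ids))

    pos0 = snps.sites["pos"].to_numpy() - 1  # 0-based
    chrom_arr = snps.sites["chrom"].to_numpy()
    gasms = []
    for rec in genes.records.sort_values(["chrom", "start"]).itertuples():
        sel = np.flatnonzero((chrom_arr == rec.chrom) & (pos0 >= rec.start) & (pos0 < rec.end))
        if sel.size == 0:
            continue
        sub = snps.matrix[:, sel]  # (n_lines, k)
        complete = ~(sub == MISSING).any(axis=1)
        if not complete.any():
            continue
        hap_strings = np.array(["".join(map(str, row)) for row in sub[complete]])
        uniq, counts = np.unique(hap_strings, return_counts=True)
        order = np.lexsort((uniq, -counts))
        alleles = [uniq[i] for i in order]
        if len(alleles) < 2:
            continue  # monomorphic
        allele_index = {h: i for i, h in enumerate(alleles)}
        codes = np.full(n_lines, -1, dtype=np.int16)
        comp_idx = np.flatnonzero(complete)
        for row_i, h in zip(comp_idx, hap_strings):
            codes[row_i] = allele_index[h]
        if missing_policy == "match_or_missing":
            allele_arrays = [np.frombuffer(a.encode(), dtype=np.uint8) - ord("0") for a in alleles]
            for row_i in np.flatnonzero(~complete):
                row = sub[row_i]
                observed = row != MISSING
                if not observed.any():
                    continue
                compatible = [
                    j for j, arr in enumerate(allele_arrays) if np.array_equal(arr[observed], row[observed])
                ]
                if len(compatible) == 1:
                    codes[row_i] = compatible[0]
        non_missing = int((codes >= 0).sum())
        if non_missing < min_lines:
            logger.info("dropping %s: only %d informative lines", rec.gene_id, non_missing)
            continue
        if len(np.unique(codes[codes >= 0])) < 2:
            continue
        gasms.append(
            GASM(
                gene_id=rec.gene_id,
                chrom=rec.chrom,
                bp_start=int(rec.start),
                site_ids=snps.sites["id"].iloc[sel].tolist(),
                alleles=alleles,
                codes=codes,
            )
        )
    if not gasms:
        logger.warning("no polymorphic markers assembled")
    return GASMSet(gasms=gasms, line_ids=list(snps.line_ids))


def gasm_summary(gasmset: GASMSet) -> dict:
    """Per-chromosome marker counts and an allele-count histogram."""
    if len(gasmset) == 0:
        logger.warning("empty marker set")
        return {"total": 0, "per_chrom": {}, "allele_histogram": {}}
    per_chrom: dict[str, int] = {}
    hist: dict[int, int] = {}
    for g in gasmset:
        per_chrom[g.chrom] = per_chrom.get(g.chrom, 0) + 1
        hist[g.n_alleles] = hist.get(g.n_alleles, 0) + 1
    return {"total": len(gasmset), "per_chrom": per_chrom, "allele_histogram": hist}


# ---------------------------------------------------------------------------
# marker TSV round trip
# ---------------------------------------------------------------------------


def write_gasm_tsv(gasmset: GASMSet, path: str | Path) -> None:
    """Write allele indices per line: gene_id, chrom, pos, alleles, then one
    column per line (NA for missing)."""
    rows = []
    for g in gasmset:
        row = {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "pos": g.bp_start,
            "alleles": "|".join(g.alleles),
        }
        for i, line in enumerate(gasmset.line_ids):
            row[line] = int(g.codes[i]) if g.codes[i] >= 0 else "NA"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gasm_tsv(path: str | Path) -> GASMSet:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    meta_cols = ["gene_id", "chrom", "pos", "alleles"]
    line_ids = [c for c in df.columns if c not in meta_cols]
    gasms = []
    for rec in df.itertuples(index=False):
        d = rec._asdict()
        codes = np.array(
            [int(d[l]) if str(d[l]) not in {"NA", "nan"} else -1 for l in line_ids], dtype=np.int16
        )
        gasms.append(
            GASM(
                gene_id=d["gene_id"],
                chrom=d["chrom"],
                bp_start=int(d["pos"]),
                site_ids=[],
                alleles=str(d["alleles"]).split("|"),
                codes=codes,
            )
        )
    return GASMSet(gasms=gasms, line_ids=line_ids)
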