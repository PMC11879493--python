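"""FPKM normalization, threshold-based DEG calling, and Venn accounting.

DEG calls follow a fixed dual-threshold rule: a gene is differentially
expressed between two sample groups when the Welch t-test on
log2(FPKM + c) across replicates gives P <= p_max *and* the group-mean
fold change satisfies |log2((mean_a + c) / (mean_b + c))| >= lfc_min
(defaults P <= 0.05, |log2FC| >= 0.807, pseudocount c = 1). No multiple-
testing correction is applied by default — the rule is the raw per-gene
threshold — though a BH-FDR switch exists.

Two contrasts (e.g. shade vs control within each of two genotypes) are
compared by exact set arithmetic: unique calls per contrast, shared calls
split into same-trend and opposite-trend, and the union total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


def fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments:
    FPKM = count * 1e9 / (length_bp * library_size), library size = column
    sum of counts."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValidationError("every gene needs a positive length")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValidationError("zero library size")
    return counts.mul(1e9).div(lengths, axis=0).div(libsize, axis=1)


def call_degs(
    fpkm_df: pd.DataFrame,
    samples: pd.DataFrame,
    group_a,
    group_b,
    p_max: float = 0.05,
    lfc_min: float = 0.807,
    pseudocount: float = 1.0,
    fdr: bool = False,
) -> pd.DataFrame:
    """Thresholded DEG calls for group_a vs group_b.

    ``group_a``/``group_b`` select samples either as (genotype, condition)
    tuples resolved against the ``samples`` sheet or as explicit sample-name
    lists; each group needs >= 2 replicates. Returns only passing genes,
    with columns gene_id, log2fc, p, direction (log2fc > 0 -> 'up' in
    group_a).
    """

    def resolve(g):
        if isinstance(g, tuple) and len(g) == 2:
            geno, cond = g
            names = samples.loc[
                (samples["genotype"] == geno) & (samples["condition"] == cond), "sample"
            ].tolist()
        else:
            names = list(g)
        if len(names) < 2:
            raise ValidationError("each group needs at least 2 replicates")
        missing = set(names) - set(fpkm_df.columns)
        if missing:
            raise ValidationError(f"samples not in matrix: {sorted(missing)}")
        return names

    a = fpkm_df[resolve(group_a)].to_numpy(float)
    b = fpkm_df[resolve(group_b)].to_numpy(float)
    c = pseudocount
    log_a = np.log2(a + c)
    log_b = np.log2(b + c)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    if fdr:
        p = stats.false_discovery_control(p, method="bh")
    lfc = np.log2((a.mean(axis=1) + c) / (b.mean(axis=1) + c))
    passing = (p <= p_max) & (np.abs(lfc) >= lfc_min)
    out = pd.DataFrame(
        {
            "gene_id": fpkm_df.index[passing],
            "log2fc": lfc[passing],
            "p": p[passing],
        }
    )
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


@dataclass
class VennPartition:
    """Two-contrast DEG set accounting with trend comparison."""

    unique_up_a: int
    unique_down_a: int
    unique_up_b: int
    unique_down_b: int
    shared_same_trend: int
    shared_opposite_trend: int

    @property
    def unique_a(self) -> int:
        return self.unique_up_a + self.unique_down_a

    @property
    def unique_b(self) -> int:
        return self.unique_up_b + self.unique_down_b

    @property
    def shared(self) -> int:
        return self.shared_same_trend + self.shared_opposite_trend

    @property
    def total_a(self) -> int:
        return self.unique_a + self.shared

    @property
    def total_b(self) -> int:
        return self.unique_b + self.shared

    @property
    def union_total(self) -> int:
        return self.unique_a + self.unique_b + self.shared


def venn_partition(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> VennPartition:
    """Exact set arithmetic over two DEG call tables (gene_id, direction)."""
    for name, calls in (("A", calls_a), ("B", calls_b)):
        if calls["gene_id"].duplicated().any():
            raise ValidationError(f"duplicate gene in call list {name}")
    dir_a = calls_a.set_index("gene_id")["direction"]
    dir_b = calls_b.set_index("gene_id")["direction"]
    set_a, set_b = set(dir_a.index), set(dir_b.index)
    only_a = set_a - set_b
    only_b = set_b - set_a
    shared = set_a & set_b
    same = sum(1 for g in shared if dir_a[g] == dir_b[g])
    return VennPartition(
        unique_up_a=sum(1 for g in only_a if dir_a[g] == "up"),
        unique_down_a=sum(1 for g in only_a if dir_a[g] == "down"),
        unique_up_b=sum(1 for g in only_b if dir_b[g] == "up"),
        unique_down_b=sum(1 for g in only_b if dir_b[g] == "down"),
        shared_same_trend=same,
        shared_opposite_trend=len(shared) - same,
    )


def up_down_totals(calls: pd.DataFrame) -> dict:
    """Per-contrast up/down/total call counts."""
    up = int((calls["direction"] == "up").sum())
    down = int((calls["direction"] == "down").sum())
    return {"up": up, "down": down, "total": up + down}


def _norm_id(g: str) -> str:
    return str(g).strip().casefold()


def intersect_gwas(calls: pd.DataFrame, gwas_genes, labels: dict | None = None) -> pd.DataFrame:
    """DEGs that are also association-mapped genes, with provenance columns.

    ``gwas_genes`` is an iterable of gene ids (or a DataFrame with a gene_id
    column, whose remaining columns are carried through); matching is
    whitespace- and case-normalized but original identifiers are reported.
    """
    if isinstance(gwas_genes, pd.DataFrame):
        gdf = gwas_genes.copy()
        if "gene_id" not in gdf.columns:
            raise ValidationError("GWAS table needs a gene_id column")
    else:
        gdf = pd.DataFrame({"gene_id": list(gwas_genes)})
    gdf["_key"] = gdf["gene_id"].map(_norm_id)
    calls = calls.copy()
    calls["_key"] = calls["gene_id"].map(_norm_id)
    merged = calls.merge(gdf.drop(columns=["gene_id"]), on="_key", how="inner").drop(columns=["_key"])
    if labels:
        for k, v in labels.items():
            merged[k] = v
    return merged.reset_index(drop=True)
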