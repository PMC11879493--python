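"""Gene–allele matrices and cross recombination-potential prediction.

The estimated allele effects of the selected markers, laid out per line in
genome order, form a gene–allele matrix: the full additive genetic
constitution of the panel for one trait. For any pair of lines the matrix
predicts the best transgressive progeny a cross could produce:

* independent-assortment model (closed form, exact): the optimal progeny
  stacks the favorable allele at every locus independently, so its value is
  mu + sum over loci of the favorable of the two parental effects;
* linkage model (seeded Monte Carlo): inbred progeny of the cross are
  simulated by map-based meiosis (Haldane, single-seed descent) and scored;
  the extreme (or a stated quantile) in the favorable direction is reported.
  Linkage can only hinder allele stacking, so the linkage-model potential is
  never more favorable than the independent-assortment value.

"Favorable" follows the trait direction: for shade-tolerance indicators
smaller is better, so potentials are minima and the summary's 10th
percentile is taken from the small-value tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .assoc import MultilocusFit
from .gasm import GASMSet
from . import simdata


@dataclass
class GeneAlleleMatrix:
    """Per-line allele-effect values for the selected markers, genome order."""

    effects: pd.DataFrame  # index line ids, columns gene ids; NaN = missing
    mu: float
    direction: str = "smaller_better"
    loci: pd.DataFrame | None = None  # gene_id, chrom, pos_cM (for linkage)

    def __post_init__(self):
        if self.direction not in {"smaller_better", "larger_better"}:
            raise ValidationError(f"unknown direction {self.direction!r}")

    @property
    def line_ids(self) -> list[str]:
        return list(self.effects.index)

    def genotypic_value(self, line: str) -> float:
        """mu + row sum, missing effects contributing 0 (population mean)."""
        row = self.effects.loc[line].to_numpy(float)
        return self.mu + float(np.nansum(row))


@dataclass
class PairPotential:
    i: str
    j: str
    model: str
    value: float
    n_missing: int = 0
    n_progeny: int | None = None
    quantile: float | None = None
    seed: int | None = None


def build_matrix(
    fit: MultilocusFit,
    gasmset: GASMSet,
    gmap: simdata.GeneticMap | None = None,
    direction: str = "smaller_better",
) -> GeneAlleleMatrix:
    """Gene–allele matrix of main-effect values per line for the fit's
    selected markers, ordered along the genome. Lines missing a marker get
    NaN there (treated as a 0 population-mean contribution downstream)."""
    genes = list(fit.gene_order)
    cols = {}
    meta = []
    for gene in genes:
        try:
            g = gasmset.by_gene(gene)
        except KeyError as exc:
            raise ValidationError(f"selected marker {gene!r} missing from genotypes") from exc
        eff = fit.allele_effects[gene]
        vals = np.where(g.codes >= 0, eff[np.clip(g.codes, 0, None)], np.nan)
        cols[gene] = vals
        pos_cM = None
        if gmap is not None:
            loc = gmap.locus(gene)
            meta.append({"gene_id": gene, "chrom": loc.chrom_id, "pos_cM": loc.pos_cM})
        else:
            meta.append({"gene_id": gene, "chrom": g.chrom, "pos_cM": np.nan})
    eff_df = pd.DataFrame(cols, index=gasmset.line_ids)
    loci = pd.DataFrame(meta, columns=["gene_id", "chrom", "pos_cM"])
    # genome order
    order = loci.sort_values(["chrom", "pos_cM"], kind="stable")["gene_id"].tolist()
    return GeneAlleleMatrix(
        effects=eff_df[order],
        mu=fit.mu,
        direction=direction,
        loci=loci.set_index("gene_id").loc[order].reset_index(),
    )


def _best(a: np.ndarray, b: np.ndarray, direction: str) -> np.ndarray:
    return np.minimum(a, b) if direction == "smaller_better" else np.maximum(a, b)


def potential_independent(matrix: GeneAlleleMatrix, i: str, j: str) -> PairPotential:
    """Closed-form free-assortment potential: mu + per-locus favorable
    parental effect. For i == j this is the line's own genotypic value."""
    ei = matrix.effects.loc[i].to_numpy(float)
    ej = matrix.effects.loc[j].to_numpy(float)
    n_missing = int(np.isnan(ei).sum() + np.isnan(ej).sum())
    ei = np.nan_to_num(ei)
    ej = np.nan_to_num(ej)
    value = matrix.mu + float(_best(ei, ej, matrix.direction).sum())
    return PairPotential(i=i, j=j, model="independent", value=value, n_missing=n_missing)


def potential_linkage(
    matrix: GeneAlleleMatrix,
    gmap: simdata.GeneticMap,
    i: str,
    j: str,
    n_progeny: int = 1000,
    generations: int = 5,
    quantile: float | None = None,
    seed: int = 0,
) -> PairPotential:
    """Monte-Carlo linkage-model potential.

    ``n_progeny`` inbred progeny of the cross i x j are simulated by
    single-seed descent over the matrix's loci using the genetic map's cM
    positions (Haldane meiosis, ``generations`` selfing rounds after the F1).
    Each progeny scores mu + the sum of its inherited parental allele-effect
    values (residual heterozygotes contribute the parental mean at that
    locus, missing parental effects contribute 0); the reported value is the
    extreme in the favorable direction, or the stated ``quantile`` (in
    percent, measured from the favorable tail).
    """
    if n_progeny < 1:
        raise ValidationError("n_progeny must be >= 1")
    genes = list(matrix.effects.columns)
    for g in genes:
        try:
            gmap.locus(g)
        except KeyError as exc:
            raise ValidationError(f"marker {g!r} absent from the genetic map") from exc
    rng = np.random.default_rng(seed)
    ei = np.nan_to_num(matrix.effects.loc[i].to_numpy(float))
    ej = np.nan_to_num(matrix.effects.loc[j].to_numpy(float))

    # group matrix loci by chromosome in map order
    by_chrom: dict[str, list[tuple[float, int]]] = {}
    for idx, g in enumerate(genes):
        loc = gmap.locus(g)
        by_chrom.setdefault(loc.chrom_id, []).append((loc.pos_cM, idx))
    scores = np.full(n_progeny, matrix.mu, dtype=float)
    for chrom_id in sorted(by_chrom):
        entries = sorted(by_chrom[chrom_id])
        pos = np.array([p for p, _ in entries])
        cols = [c for _, c in entries]
        r_adj = simdata.haldane(np.diff(pos))
        L = len(cols)
        hap_a = np.zeros((n_progeny, L), dtype=np.int8)  # parent i gamete
        hap_b = np.ones((n_progeny, L), dtype=np.int8)  # parent j gamete
        for _ in range(generations):
            new_a = simdata._gamete(hap_a, hap_b, r_adj, rng)
            new_b = simdata._gamete(hap_a, hap_b, r_adj, rng)
            hap_a, hap_b = new_a, new_b
        e_i = ei[cols]
        e_j = ej[cols]
        val_a = np.where(hap_a == 0, e_i, e_j)
        val_b = np.where(hap_b == 0, e_i, e_j)
        scores += ((val_a + val_b) / 2.0).sum(axis=1)

    smaller = matrix.direction == "smaller_better"
    if quantile is None:
        value = float(scores.min() if smaller else scores.max())
    else:
        q = quantile if smaller else 100.0 - quantile
        value = float(np.percentile(scores, q))
    return PairPotential(
        i=i, j=j, model="linkage", value=value,
        n_missing=int(np.isnan(matrix.effects.loc[i]).sum() + np.isnan(matrix.effects.loc[j]).sum()),
        n_progeny=n_progeny, quantile=quantile, seed=seed,
    )


@dataclass
class PotentialSummary:
    n_lines: int
    n_pairs: int
    model: str
    direction: str
    percentiles: dict[float, float]
    p10_favorable: float
    best: float
    values: pd.DataFrame  # columns i, j, value


def summarize_pairs(
    matrix: GeneAlleleMatrix,
    gmap: simdata.GeneticMap | None = None,
    model: str = "independent",
    n_progeny: int = 200,
    generations: int = 5,
    quantile: float | None = None,
    seed: int = 0,
    percentiles: tuple[float, ...] = (1, 5, 10, 25, 50, 75, 90, 95, 99),
) -> PotentialSummary:
    """Potentials for all n(n-1)/2 unordered line pairs with a percentile
    table; the 10th percentile is reported from the favorable tail."""
    lines = matrix.line_ids
    n = len(lines)
    if n < 2:
        raise ValidationError("need at least two lines")
    smaller = matrix.direction == "smaller_better"

    if model == "independent":
        E = np.nan_to_num(matrix.effects.to_numpy(float))
        total = np.full((n, n), matrix.mu)
        for l in range(E.shape[1]):
            col = E[:, l]
            pair = np.minimum(col[:, None], col[None, :]) if smaller else np.maximum(col[:, None], col[None, :])
            total += pair
        iu, ju = np.triu_indices(n, k=1)
        vals = total[iu, ju]
        pairs = pd.DataFrame({"i": [lines[a] for a in iu], "j": [lines[b] for b in ju], "value": vals})
    elif model == "linkage":
        if gmap is None:
            raise ValidationError("linkage model needs a genetic map")
        rows = []
        rng = np.random.default_rng(seed)
        for a in range(n):
            for b in range(a + 1, n):
                pp = potential_linkage(
                    matrix, gmap, lines[a], lines[b],
                    n_progeny=n_progeny, generations=generations,
                    quantile=quantile, seed=int(rng.integers(0, 2**31 - 1)),
                )
                rows.append({"i": lines[a], "j": lines[b], "value": pp.value})
        pairs = pd.DataFrame(rows)
        vals = pairs["value"].to_numpy()
    else:
        raise ValidationError(f"unknown model {model!r}")

    pct = {float(p): float(np.percentile(vals, p)) for p in percentiles}
    p10 = float(np.percentile(vals, 10.0 if smaller else 90.0))
    best = float(vals.min() if smaller else vals.max())
    return PotentialSummary(
        n_lines=n,
        n_pairs=n * (n - 1) // 2,
        model=model,
        direction=matrix.direction,
        percentiles=pct,
        p10_favorable=p10,
        best=best,
        values=pairs,
    )
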