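"""Synthetic biparental RIL populations, phenotypes, and expression matrices.

This module generates data with the statistical structure the downstream
analyses assume, so that every stage of the pipeline can be exercised and
validated without external data:

* a genetic map of annotated gene loci with cM and bp coordinates,
* recombinant inbred lines (RILs) produced by single-seed descent from an
  F1 of two fully inbred parents, with meiosis driven by the Haldane map
  function (no crossover interference),
* multi-environment quantitative phenotypes with additive QTL effects,
  locus-by-environment interaction (GEI) effects, and plot-level noise
  solved so that the realized broad-sense heritability matches a target,
* negative-binomial RNA-seq count matrices with planted differential
  expression, and
* a scale-free scored interaction edge list for network post-processing.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

# haplotype source codes used throughout the package
P1 = 0
P2 = 1
HET = 2
MISSING = -1

#: physical scale used to place gene intervals on the map (bp per cM).
BP_PER_CM = 400_000
#: span of a simulated gene body in bp.
GENE_SPAN_BP = 3_000


def haldane(d_cM):
    """Recombination fraction for a map distance in cM, Haldane mapping.

    r = (1 - exp(-2 d / 100)) / 2; no interference.
    """
    d = np.asarray(d_cM, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def ril_recombination_fraction(r):
    """Expected recombinant-line fraction R = 2r / (1 + 2r) for selfed RILs.

    This is the classical single-seed-descent limit (complete inbreeding)
    for a per-meiosis recombination fraction ``r``.
    """
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    chrom_id: str
    length_cM: float


@dataclass(frozen=True)
class Locus:
    """One annotated gene on the map.

    ``bp_start``/``bp_end`` are 0-based half-open physical coordinates.
    """

    gene_id: str
    chrom_id: str
    pos_cM: float
    bp_start: int
    bp_end: int
    n_snps: int


@dataclass
class GeneticMap:
    chromosomes: list[Chromosome]
    loci: list[Locus]

    def __post_init__(self):
        seen = set()
        chrom_lengths = {c.chrom_id: c.length_cM for c in self.chromosomes}
        last: dict[str, float] = {}
        last_bp: dict[str, int] = {}
        for loc in self.loci:
            if loc.gene_id in seen:
                raise ConfigError(f"duplicate gene_id {loc.gene_id!r}")
            seen.add(loc.gene_id)
            if loc.chrom_id not in chrom_lengths:
                raise ConfigError(f"locus {loc.gene_id} on unknown chromosome")
            if not 0.0 <= loc.pos_cM <= chrom_lengths[loc.chrom_id]:
                raise ConfigError(f"locus {loc.gene_id} outside its chromosome")
            if loc.chrom_id in last and loc.pos_cM <= last[loc.chrom_id]:
                raise ConfigError("loci must be strictly increasing in cM")
            if loc.chrom_id in last_bp and loc.bp_start < last_bp[loc.chrom_id]:
                raise ConfigError("bp intervals must not overlap")
            last[loc.chrom_id] = loc.pos_cM
            last_bp[loc.chrom_id] = loc.bp_end
            if loc.n_snps < 1:
                raise ConfigError("every locus needs >= 1 SNP")

    @property
    def gene_ids(self) -> list[str]:
        return [l.gene_id for l in self.loci]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def loci_for(self, chrom_id: str) -> list[Locus]:
        return [l for l in self.loci if l.chrom_id == chrom_id]

    def locus(self, gene_id: str) -> Locus:
        for l in self.loci:
            if l.gene_id == gene_id:
                return l
        raise KeyError(gene_id)

    def loci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [l.gene_id for l in self.loci],
                "chrom": [l.chrom_id for l in self.loci],
                "pos_cM": [l.pos_cM for l in self.loci],
                "bp_start": [l.bp_start for l in self.loci],
                "bp_end": [l.bp_end for l in self.loci],
                "n_snps": [l.n_snps for l in self.loci],
            }
        )


def make_map(
    n_chrom: int,
    genes_per_chrom: int,
    chrom_length_cM: float = 120.0,
    snps_per_gene: int | tuple[int, int] = (1, 4),
    seed: int = 0,
) -> GeneticMap:
    """Lay out ``genes_per_chrom`` gene loci per chromosome with jittered
    uniform spacing.

    ``snps_per_gene`` is either a fixed count or an inclusive (lo, hi) range
    drawn per gene. Deterministic for a fixed seed.
    """
    if n_chrom < 1 or genes_per_chrom < 1:
        raise ConfigError("n_chrom and genes_per_chrom must be >= 1")
    if chrom_length_cM <= 0:
        raise ConfigError("chrom_length_cM must be > 0")
    if isinstance(snps_per_gene, int):
        lo = hi = snps_per_gene
    else:
        lo, hi = snps_per_gene
    if lo < 1 or hi < lo:
        raise ConfigError("snps_per_gene must be >= 1")

    rng = np.random.default_rng(seed)
    chroms = []
    loci = []
    spacing = chrom_length_cM / genes_per_chrom
    for c in range(n_chrom):
        chrom_id = f"chr{c + 1:02d}"
        chroms.append(Chromosome(chrom_id, chrom_length_cM))
        base = (np.arange(genes_per_chrom) + 0.5) * spacing
        # jitter < 0.3 * spacing keeps positions ordered and in range
        pos = base + rng.uniform(-0.3, 0.3, size=genes_per_chrom) * spacing
        for g in range(genes_per_chrom):
            n_snps = int(rng.integers(lo, hi + 1))
            bp_start = int(round(pos[g] * BP_PER_CM))
            loci.append(
                Locus(
                    gene_id=f"g{c + 1:02d}g{g + 1:03d}",
                    chrom_id=chrom_id,
                    pos_cM=float(pos[g]),
                    bp_start=bp_start,
                    bp_end=bp_start + GENE_SPAN_BP,
                    n_snps=n_snps,
                )
            )
    return GeneticMap(chroms, loci)


# ---------------------------------------------------------------------------
# RIL simulation (single-seed descent)
# ---------------------------------------------------------------------------


@dataclass
class RILGenotypes:
    """Per-line haplotype sources and SNP alleles for a simulated RIL panel.

    ``sources`` is (n_lines, n_loci) with codes ``P1``/``P2``/``HET``/
    ``MISSING``; ``snp_alleles`` is (n_lines, n_snp_sites) coded 0/1 with -1
    for missing (residual heterozygotes are scored missing at the SNP level).
    """

    line_ids: list[str]
    gene_ids: list[str]
    sources: np.ndarray
    snp_sites: pd.DataFrame  # columns: chrom, pos (1-based bp), id, locus
    snp_alleles: np.ndarray
    generation: str

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


def _gamete(hap_a: np.ndarray, hap_b: np.ndarray, r_adj: np.ndarray, rng) -> np.ndarray:
    """One gamete per row from a diploid (hap_a, hap_b), Haldane crossovers."""
    n, L = hap_a.shape
    start = rng.integers(0, 2, size=n)
    if L > 1:
        cross = rng.random((n, L - 1)) < r_adj
        which = (start[:, None] + np.concatenate(
            [np.zeros((n, 1), dtype=int), np.cumsum(cross, axis=1)], axis=1
        )) % 2
    else:
        which = start[:, None]
    return np.where(which == 0, hap_a, hap_b)


def simulate_rils(
    gmap: GeneticMap,
    n_lines: int,
    n_selfing_gens: int = 6,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> RILGenotypes:
    """Single-seed descent from the F1 of two inbred parents.

    Each of ``n_selfing_gens`` generations replaces every line by one selfed
    offspring (two independent gametes from the same plant). The default of 6
    selfing rounds after the F1 yields F7 lines with residual heterozygosity
    near 2**-6 per locus. Loci are inherited atomically: all SNPs within a
    gene share the gene's haplotype source (gene bodies span ~0.01 cM at the
    package's physical scale, so intra-gene crossovers are negligible).
    """
    if gmap.n_loci == 0:
        raise ConfigError("empty genetic map")
    if n_lines < 2:
        raise ConfigError("n_lines must be >= 2")
    if n_selfing_gens < 1:
        raise ConfigError("n_selfing_gens must be >= 1")

    rng = np.random.default_rng(seed)
    blocks = []
    for chrom in gmap.chromosomes:
        loci = gmap.loci_for(chrom.chrom_id)
        if not loci:
            continue
        pos = np.array([l.pos_cM for l in loci])
        r_adj = haldane(np.diff(pos))
        L = len(loci)
        hap_a = np.zeros((n_lines, L), dtype=np.int8)  # P1 gamete
        hap_b = np.ones((n_lines, L), dtype=np.int8)  # P2 gamete
        for _ in range(n_selfing_gens):
            new_a = _gamete(hap_a, hap_b, r_adj, rng)
            new_b = _gamete(hap_a, hap_b, r_adj, rng)
            hap_a, hap_b = new_a, new_b
        src = np.where(hap_a == hap_b, hap_a, np.int8(HET))
        blocks.append(src)
    sources = np.concatenate(blocks, axis=1)

    # expand loci to SNP sites; SNP allele = source (0/1), HET -> missing
    site_rows = []
    allele_cols = []
    for idx, loc in enumerate(gmap.loci):
        span = loc.bp_end - loc.bp_start
        offsets = np.round(span * (np.arange(loc.n_snps) + 1) / (loc.n_snps + 1)).astype(int)
        col = sources[:, idx].astype(np.int8)
        col = np.where((col == P1) | (col == P2), col, np.int8(MISSING))
        for off in offsets:
            pos_bp = loc.bp_start + int(off) + 1  # 1-based
            site_rows.append(
                {"chrom": loc.chrom_id, "pos": pos_bp, "id": f"{loc.chrom_id}_{pos_bp}", "locus": idx}
            )
            allele_cols.append(col)
    snp_alleles = np.stack(allele_cols, axis=1)
    if missing_rate > 0:
        mask = rng.random(snp_alleles.shape) < missing_rate
        snp_alleles = np.where(mask, np.int8(MISSING), snp_alleles)

    line_ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    return RILGenotypes(
        line_ids=line_ids,
        gene_ids=gmap.gene_ids,
        sources=sources,
        snp_sites=pd.DataFrame(site_rows),
        snp_alleles=snp_alleles,
        generation=f"F{n_selfing_gens + 1}",
    )


# ---------------------------------------------------------------------------
# trait architecture and phenotypes
# ---------------------------------------------------------------------------


@dataclass
class QTLEffect:
    gene_id: str
    a: float  # additive effect in trait units (deviation-coded: P1 = +a, P2 = -a)
    gei: np.ndarray  # per-environment deviation effects, sum to 0


@dataclass
class TraitArchitecture:
    qtl: list[QTLEffect]
    mu: float
    h2_main: float
    h2_gei: float
    n_env: int
    n_rep: int

    def __post_init__(self):
        if not (0.0 <= self.h2_main < 1.0) or not (0.0 <= self.h2_gei < 1.0):
            raise ConfigError("heritability targets must be in [0, 1)")
        if self.h2_main + self.h2_gei >= 1.0:
            raise ConfigError("h2_main + h2_gei must be < 1")
        for q in self.qtl:
            q.gei = np.asarray(q.gei, dtype=float)
            if q.gei.shape != (self.n_env,):
                raise ConfigError("GEI effect vector must have one entry per environment")
            if not np.all(np.isfinite(q.gei)) or not math.isfinite(q.a):
                raise ConfigError("effects must be finite")
            if abs(q.gei.sum()) > 1e-8 * max(1.0, np.abs(q.gei).max()):
                raise ConfigError("GEI effects must sum to 0 across environments")


def assign_architecture(
    gmap: GeneticMap,
    n_qtl: int,
    effect_sd: float = 0.06,
    gei_sd: float = 0.04,
    h2_main: float = 0.6717,
    h2_gei: float = 0.1802,
    n_env: int = 3,
    n_rep: int = 3,
    mu: float = 1.6,
    seed: int = 0,
) -> TraitArchitecture:
    """Sample a QTL architecture: genes without replacement, additive effects
    from N(0, effect_sd^2), environment-centered GEI effects from
    N(0, gei_sd^2)."""
    if n_qtl > gmap.n_loci:
        raise ConfigError("n_qtl exceeds number of loci on the map")
    rng = np.random.default_rng(seed)
    genes = list(rng.choice(gmap.gene_ids, size=n_qtl, replace=False)) if n_qtl else []
    qtl = []
    for g in genes:
        a = float(rng.normal(0.0, effect_sd))
        if gei_sd > 0:
            ge = rng.normal(0.0, gei_sd, size=n_env)
            ge = ge - ge.mean()
        else:
            ge = np.zeros(n_env)
        qtl.append(QTLEffect(gene_id=g, a=a, gei=ge))
    return TraitArchitecture(qtl=qtl, mu=mu, h2_main=h2_main, h2_gei=h2_gei, n_env=n_env, n_rep=n_rep)


@dataclass
class SimPhenotypes:
    """Simulated phenotype records plus the latent truth used to build them."""

    plots: pd.DataFrame
    cells: pd.DataFrame | None
    truth: dict


def genotype_scores(rils: RILGenotypes, gene_ids: Sequence[str]) -> np.ndarray:
    """Signed genotype scores x in {+1 (P1), -1 (P2), 0 (HET/missing)} for
    the given genes, shape (n_lines, n_genes)."""
    index = {g: i for i, g in enumerate(rils.gene_ids)}
    cols = []
    for g in gene_ids:
        if g not in index:
            raise KeyError(f"gene {g!r} not in genotypes")
        src = rils.sources[:, index[g]]
        cols.append(np.where(src == P1, 1.0, np.where(src == P2, -1.0, 0.0)))
    if not cols:
        return np.zeros((rils.n_lines, 0))
    return np.stack(cols, axis=1)


def simulate_phenotypes(
    rils: RILGenotypes,
    arch: TraitArchitecture,
    mode: str = "indicator",
    seed: int = 0,
    env_main_sd: float = 0.02,
    nn_range: tuple[int, int] = (10, 15),
    ph_base_mean: float = 80.0,
    ph_base_sd: float = 8.0,
) -> SimPhenotypes:
    """Emit plot-level indicator values (or back-constructed raw records).

    The plot model is ``y_ier = mu + G_i + E_e + GE_ie + eps_ier`` with
    G from the architecture's additive effects, GE rescaled and eps solved so
    that the realized heritability partition (two-way random-model formula,
    denominator sigma2_g + sigma2_ge/n + sigma2_eps/(n r)) matches the
    architecture's targets in expectation.

    In ``raw`` mode, plant height / node number pairs are back-constructed so
    that the shade-tolerance index computed from them reproduces the latent
    plot indicator exactly: node numbers are equal across conditions, control
    heights come from a baseline distribution, and shade height equals
    control height times the latent indicator.
    """
    if mode not in {"indicator", "raw"}:
        raise ConfigError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n_env, n_rep = arch.n_env, arch.n_rep
    x = genotype_scores(rils, [q.gene_id for q in arch.qtl])
    a = np.array([q.a for q in arch.qtl])
    G = x @ a if len(a) else np.zeros(rils.n_lines)
    var_g = float(G.var(ddof=1)) if rils.n_lines > 1 else 0.0

    gmat = np.stack([q.gei for q in arch.qtl], axis=0) if arch.qtl else np.zeros((0, n_env))
    GE = x @ gmat if len(a) else np.zeros((rils.n_lines, n_env))
    ms_ge = float((GE**2).mean()) if GE.size else 0.0
    h2_gei_eff = arch.h2_gei if (ms_ge > 0 and arch.h2_gei > 0 and n_env > 1) else 0.0

    # Calibrate noise scales so the expected-mean-square ANOVA estimates of
    # (sigma2_g, sigma2_ge, sigma2_eps) land on the heritability targets in
    # expectation. Because GEI effects are environment-centered, every
    # line's GEI contributions sum to zero: line means carry none of the
    # interaction variance, so the EMS subtraction attributes sigma2_ge/n of
    # the line-mean variance away from sigma2_g — hence the denominator D
    # solves var_g = (h2_main + h2_gei) * D. Likewise the interaction mean
    # square recovers n/(n-1) times the flat GEI mean square.
    if var_g > 0 and arch.h2_main + h2_gei_eff > 0:
        D = var_g / (arch.h2_main + h2_gei_eff)
        h2_main_eff = arch.h2_main
    else:
        D = 1.0
        h2_main_eff = 0.0
        h2_gei_eff = 0.0

    if h2_gei_eff > 0:
        target_ms = h2_gei_eff * D * (n_env - 1)
        GE = GE * math.sqrt(target_ms / ms_ge)
    else:
        GE = np.zeros_like(GE) if GE.size else GE

    sigma2_eps = max(D * (1.0 - h2_main_eff - h2_gei_eff) * n_env * n_rep, 0.0)
    env_effects = rng.normal(0.0, env_main_sd, size=n_env) if env_main_sd > 0 else np.zeros(n_env)

    lines = np.repeat(np.arange(rils.n_lines), n_env * n_rep)
    envs = np.tile(np.repeat(np.arange(n_env), n_rep), rils.n_lines)
    reps = np.tile(np.arange(n_rep), rils.n_lines * n_env)
    eps = rng.normal(0.0, math.sqrt(sigma2_eps), size=lines.shape[0]) if sigma2_eps > 0 else np.zeros(lines.shape[0])
    y = arch.mu + G[lines] + env_effects[envs] + GE[lines, envs] + eps

    plots = pd.DataFrame(
        {
            "line": [rils.line_ids[i] for i in lines],
            "env": [f"E{e + 1}" for e in envs],
            "rep": reps + 1,
            "value": y,
        }
    )
    truth = {
        "genetic_values": pd.Series(G, index=rils.line_ids),
        "gei_values": pd.DataFrame(GE, index=rils.line_ids, columns=[f"E{e + 1}" for e in range(n_env)]),
        "sigma2_eps": sigma2_eps,
        "phenotypic_denominator": D,
        "h2_main": h2_main_eff,
        "h2_gei": h2_gei_eff,
        "latent": plots.copy(),
    }

    if mode == "indicator":
        return SimPhenotypes(plots=plots, cells=None, truth=truth)

    # raw mode: back-construct PH/NN so compute_sti recovers the latent value
    lo, hi = nn_range
    if lo < 1:
        raise ConfigError("node-number baseline must be >= 1")
    if np.any(y <= 0):
        raise ConfigError("latent indicator non-positive; raw back-construction undefined")
    nn_per_line = rng.integers(lo, hi + 1, size=rils.n_lines)
    ph_ck = np.clip(rng.normal(ph_base_mean, ph_base_sd, size=y.shape[0]), 1.0, None)
    ph_shade = ph_ck * y
    rows = []
    for k in range(y.shape[0]):
        base = {
            "line": rils.line_ids[lines[k]],
            "env": f"E{envs[k] + 1}",
            "rep": int(reps[k] + 1),
            "NN": int(nn_per_line[lines[k]]),
        }
        rows.append({**base, "condition": "control", "PH": float(ph_ck[k])})
        rows.append({**base, "condition": "shade", "PH": float(ph_shade[k])})
    raw = pd.DataFrame(rows, columns=["line", "env", "rep", "condition", "PH", "NN"])
    return SimPhenotypes(plots=raw, cells=None, truth=truth)


def build_cell_records(
    latent: pd.DataFrame,
    seed: int = 0,
    control_mean_um: float = 40.0,
    n_control_images: int = 8,
    cells_per_image: int = 20,
    cv: float = 0.1,
) -> pd.DataFrame:
    """Back-construct pith-cell length micrograph records from latent relative
    cell-length values.

    ``latent`` has columns line, rep, value; each (line, rep) becomes one
    shade micrograph whose mean cell length equals value times the line's
    pooled control mean exactly (cells are rescaled to hit the target mean),
    so computing the relative cell length downstream recovers the latent
    values to machine precision.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for line, grp in latent.groupby("line", sort=True):
        # control micrographs, pooled mean pinned to control_mean_um
        ctrl = rng.normal(control_mean_um, cv * control_mean_um, size=(n_control_images, cells_per_image))
        ctrl = np.clip(ctrl, 1.0, None)
        ctrl *= control_mean_um / ctrl.mean()
        for im in range(n_control_images):
            for length in ctrl[im]:
                rows.append({"line": line, "condition": "control", "image_id": f"ck{im + 1}", "length": float(length)})
        for _, rec in grp.iterrows():
            target = rec["value"] * control_mean_um
            cells = np.clip(rng.normal(target, cv * max(target, 1e-6), size=cells_per_image), 1e-6, None)
            cells *= target / cells.mean()
            for length in cells:
                rows.append(
                    {"line": line, "condition": "shade", "image_id": f"s{int(rec['rep'])}", "length": float(length)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


@dataclass
class SimExpression:
    counts: pd.DataFrame  # genes x samples, integer
    lengths: pd.Series  # gene length in bp
    samples: pd.DataFrame  # sample, genotype, condition, rep
    truth: pd.DataFrame  # gene, contrast, is_de, true_lfc


def simulate_expression(
    n_genes: int = 2000,
    de_fraction: float = 0.1,
    lfc_range: tuple[float, float] = (1.0, 3.0),
    dispersion: float = 0.1,
    mean_range: tuple[float, float] = (20.0, 2000.0),
    n_rep: int = 3,
    seed: int = 0,
    genotypes: tuple[str, str] = ("G", "Z"),
    conditions: tuple[str, str] = ("S", "CK"),
    gene_ids: Sequence[str] | None = None,
) -> SimExpression:
    """Negative-binomial counts for 2 genotypes x 2 conditions x n_rep.

    For each genotype contrast (shade vs control), a ``de_fraction`` of genes
    gets a planted log2 fold change with random sign drawn from ``lfc_range``
    (applied to the shade condition mean). ``dispersion`` is the NB
    gene-level dispersion (0 gives Poisson counts).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ConfigError("de_fraction must be in [0, 1]")
    if lfc_range[0] < 0 or lfc_range[1] < lfc_range[0]:
        raise ConfigError("lfc_range must be nonnegative and ordered")
    if dispersion < 0:
        raise ConfigError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"Gene{i + 1:05d}" for i in range(n_genes)]
    else:
        gene_ids = list(gene_ids)
        if len(gene_ids) != n_genes:
            raise ConfigError("gene_ids length must equal n_genes")
    lengths = pd.Series(rng.integers(500, 5001, size=n_genes), index=gene_ids, name="length")
    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_genes))

    shade, control = conditions
    sample_rows = []
    truth_rows = []
    count_cols: dict[str, np.ndarray] = {}
    for geno in genotypes:
        n_de = int(round(de_fraction * n_genes))
        de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
        lfc = np.zeros(n_genes)
        if n_de:
            mags = rng.uniform(lfc_range[0], lfc_range[1], size=n_de)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            lfc[de_idx] = mags * signs
        is_de = np.zeros(n_genes, dtype=bool)
        is_de[de_idx] = True
        contrast = f"{geno}_{shade}_vs_{control}"
        for g, gid in enumerate(gene_ids):
            truth_rows.append({"gene": gid, "contrast": contrast, "is_de": bool(is_de[g]), "true_lfc": float(lfc[g])})
        for cond in (shade, control):
            mean = base * np.exp2(lfc) if cond == shade else base
            for rep in range(1, n_rep + 1):
                name = f"{geno}_{cond}_{rep}"
                if dispersion > 0:
                    n_param = 1.0 / dispersion
                    p_param = n_param / (n_param + mean)
                    counts = rng.negative_binomial(n_param, p_param)
                else:
                    counts = rng.poisson(mean)
                count_cols[name] = counts.astype(np.int64)
                sample_rows.append({"sample": name, "genotype": geno, "condition": cond, "rep": rep})

    counts = pd.DataFrame(count_cols, index=gene_ids)
    samples = pd.DataFrame(sample_rows)
    truth = pd.DataFrame(truth_rows)
    return SimExpression(counts=counts, lengths=lengths, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# interaction edge list (for network post-processing demos)
# ---------------------------------------------------------------------------


def simulate_ppi_edges(
    genes: Sequence[str],
    m: int = 2,
    seed: int = 0,
    score_range: tuple[float, float] = (0.05, 0.99),
) -> pd.DataFrame:
    """Scale-free scored edge list over the given genes (preferential
    attachment), with uniform confidence scores spanning ``score_range`` so a
    score filter has something to remove."""
    import networkx as nx

    genes = list(genes)
    if len(genes) <= m:
        raise ConfigError("need more genes than the attachment parameter m")
    g = nx.barabasi_albert_graph(len(genes), m, seed=int(seed))
    rng = np.random.default_rng(seed)
    rows = []
    for u, v in sorted(g.edges()):
        rows.append(
            {
                "node_a": genes[u],
                "node_b": genes[v],
                "score": float(rng.uniform(*score_range)),
            }
        )
    return pd.DataFrame(rows)
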