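# shadenet

A Python toolkit for dissecting quantitative shade tolerance in a
biparental recombinant-inbred-line (RIL) soybean population — from raw
field phenotypes through a multi-allelic haplotype-marker association scan
to cross planning, differential expression, and interaction-network
statistics. Every stage is paired with a seeded synthetic-data generator,
so the whole workflow is testable end to end without any external data.

It is written for quantitative geneticists and breeders who work with
inter/relay-cropped soybean (or any crop where a trait is scored as a
shade/control ratio) and want the complete gene–allele system of a trait
rather than a handful of top hits.

## The model

**Indicators.** Shade tolerance is scored by two dimensionless ratios,
both *smaller = more tolerant*:

- shade-tolerance index, per matched shade/control plot pair
  `STI = (PH_shade/PH_ck + AINL_shade/AINL_ck) / 2`,
  with `AINL = PH / NN` (plant height over main-stem node number);
- relative pith cell length, per shade micrograph
  `RCL = CL_shade / ACL_ck`, the mean cell length of a shade micrograph
  over the pooled mean of all control-micrograph cells.

**Heritability.** Variance components come from the expected mean squares
of the balanced two-way random model (lines × environments × replicates);
broad-sense heritability on a line-mean basis is

```
h² = σ²_g / (σ²_g + σ²_ge/n + σ²_ε/(n r))
```

split into a main share `σ²_g/D` and an interaction share `(σ²_ge/n)/D`
that add to the total (single-environment traits use the reduced
denominator `σ²_g + σ²_ε/r`).

**Markers and the scan.** All SNPs inside one annotated gene are
concatenated into a multi-allelic *gene–allele marker* (two alleles in a
biparental panel; recombinant haplotypes add more). The association scan
is restricted and two-stage: (1) a single-locus screen keeps markers with
P ≤ 0.05; (2) deterministic forward/backward stepwise regression under a
multilocus model — with optional marker × environment interaction terms —
enters markers at the experiment-wise level α/m and caps the summed
contribution at the trait's heritability. Per-marker contributions
(sequential R², % of phenotypic variance) classify genes as
large-contribution (≥ 1.5%) or small-contribution, and heritability not
covered by mapped genes is the unmapped-polygene remainder.

**Cross planning.** The estimated allele effects form a gene–allele
matrix; for every pair of lines the best achievable transgressive progeny
is predicted under free assortment (closed form:
`μ + Σ_l best(e_il, e_jl)`) and under a linkage model (seeded Monte-Carlo
single-seed-descent progeny over the genetic map, Haldane mapping). The
10th percentile of pair potentials, taken from the favorable tail,
summarizes a panel's crossing prospects.

**Expression and networks.** DEGs are called by a dual threshold
(Welch-t P ≤ 0.05 on log2(FPKM+1) and |log2FC| ≥ 0.807); two contrasts are
compared by exact Venn accounting with trend splits. Interaction edge
lists are filtered at score ≥ 0.18, nodes with more than 10 links are key
hubs, oversized gene sets are split into even random groups of ≤ 2000, and
the top-five hubs per group (ties included) form a meta-network.

## Worked example

`examples/` holds one short script per capability. The association-scan
example simulates a 246-line F7 panel with six planted QTL, writes and
re-reads VCF + GFF3, assembles markers and runs the two-stage scan:

```
$ python examples/03_marker_gwas.py
assembled 50 markers from 106 SNPs ({2: 50} alleles per marker)
stage 1 kept 29 markers; stage 2 selected 4
gene_id  r2_main_pct  r2_gei_pct class
g05g001    28.160872    1.542242    LC
g01g004    13.591244   13.495982    LC
g02g002     4.990726    0.883746    LC
g04g007     3.517498    3.434057    LC
planted QTL: ['g01g004', 'g01g009', 'g02g002', 'g04g007', 'g05g001', 'g05g009']
mapped 50.26% of PV (4 LC + 0 SC genes); polygene remainder 17.29%
```

Every selected gene is a planted QTL (the two missed ones have the
smallest effects and fall to the polygene remainder), each line lists a
gene's main and interaction contribution in % of phenotypic variance with
its LC/SC class, and the mapped total respects the heritability cap.

The heritability example prints the partition the generator was asked
for:

```
$ python examples/02_indicators_heritability.py
2214 plot-level STI values; mean 1.622 (smaller = more shade tolerant)
variance components: sigma2_g=0.0268, sigma2_ge=0.0181, sigma2_eps=0.0536
heritability: main 69.14% + GEI 15.53% = total 84.67%
genotypic CV: 10.10%
```

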