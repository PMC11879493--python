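# Methods

This note documents the models implemented in `shadenet`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions made where the design was open.

## Population simulation

RIL panels are generated by single-seed descent: an F1 between two fully
inbred parents is selfed for `n_selfing_gens` rounds (default 6, giving F7
lines with residual heterozygosity ≈ 2⁻⁶ per locus), keeping one offspring
per generation. Meiosis uses the **Haldane map function**
`r = (1 − e^(−2d/100))/2` with no crossover interference — the simplest
self-consistent choice, and the one the closed-form checks assume. The
expected recombinant-line fraction between two loci in the fully inbred
limit is `R = 2r/(1+2r)`; the test suite verifies this across a 1–50 cM
grid within Monte-Carlo error.

Gene loci are inherited atomically: all SNPs inside a gene carry the
gene's haplotype source. At the package's physical scale (400 kb/cM, 3 kb
gene bodies) a gene spans ~0.0075 cM, so intra-gene crossovers are
negligible over six selfing meioses; multi-allele marker behaviour is
exercised with constructed recombinant fixtures instead. Residual
heterozygotes are scored `HET` at the locus and missing at the SNP level;
generation is a parameter, not an assertion, since real residual
heterozygosity depends on line development details the analysis does not
need.

## Phenotype generation and heritability calibration

Plot values follow `y_ier = μ + G_i + E_e + GE_ie + ε_ier` with additive
QTL effects (`x ∈ {+1, −1, 0}` for parent-1, parent-2, heterozygous or
missing), environment-centered interaction effects, and i.i.d. normal
plot error. The default effect scale (`effect_sd = 0.06` trait units,
`μ = 1.6`) keeps indicator values in the realistic 1.1–2.3 band of a
shade/control ratio index — a ratio of plant heights cannot be non-positive,
and the raw-record back-construction enforces that.

The noise scales are solved so that the **estimated** heritability
partition matches the targets in expectation, not merely the generative
one. Two estimator facts matter:

- interaction effects are deviation-coded (they sum to zero across
  environments within each line), so line means carry no interaction
  variance; the expected-mean-square subtraction then attributes
  `σ²_ge/n` of the line-mean variance away from `σ²_g`, and the generator
  compensates by solving `var(G) = (h²_main + h²_gei) · D`;
- for the same reason the two-way interaction mean square recovers
  `n/(n−1)` times the flat mean square of the interaction effects, so the
  GEI effects are rescaled to `h²_gei · D · (n−1)`.

A 200-replicate calibration test confirms the estimated partition lands
within ±0.03 of the targets (0.67 main + 0.18 interaction) for a 246-line
panel with 3 environments × 3 replicates.

Raw-mode back-construction fixes node numbers per line (equal in shade
and control), draws control heights from a baseline distribution, and
sets shade height to control height times the latent indicator: computing
the index from the emitted records reproduces the latent value to
machine precision (the same trick, with per-micrograph rescaling, yields
pith-cell records whose relative cell lengths are exact).

## Variance components

`anova_components` uses method-of-moments estimates from the balanced
two-way random model: `σ²_ε = MS_err`, `σ²_ge = (MS_GE − MS_err)/r`,
`σ²_g = (MS_G − MS_GE)/(nr)`; single-environment tables reduce to the
one-way model with `σ²_ge` not estimable (reported 0, flagged). Negative
moment estimates are truncated at zero and flagged — standard EMS
practice. Unbalanced layouts are rejected rather than approximated,
because the reference design is balanced and unbalanced EMS coefficients
would silently change the heritability denominator.

## Marker assembly

Within-gene haplotype strings are read in ascending bp on the reference
orientation (strand ignored). Distinct complete haplotypes become
alleles, ordered by descending frequency then lexicographically — a
deterministic convention. The default missing policy,
**match-or-missing**, assigns an incomplete haplotype only when exactly
one observed complete haplotype is compatible; anything ambiguous is
missing. Residual heterozygotes are missing at the marker (RIL analyses
conventionally drop them). Markers are dropped when monomorphic or when
fewer than 80% of lines are informative (`min_lines` exposes the knob).
Coordinates: VCF/GFF3 1-based closed, BED 0-based half-open, internal
0-based half-open. Gene-body intervals are used as annotated; a wider
window can be emulated by widening the annotation.

## The two-stage scan

Stage 1 screens each marker with a fixed-effect F-test (environment as a
blocking factor when multi-environment data are supplied; interaction is
not screened — the screen stays cheap and conservative). Stage 2 is
deterministic forward/backward stepwise regression:

- candidate terms are marker main effects, plus marker × environment
  terms for markers already in the model (hierarchy), with main terms
  shielded from backward removal while their interaction term remains;
- entry and stay use partial-F tests at the **experiment-wise** level
  `α₂/m`, where `m` is the number of markers the experiment scanned
  (`m_total`). A raw per-test 0.05 level would re-admit essentially every
  stage-1 survivor under a null trait, since a candidate's first partial
  F is its marginal test; dividing by `m` reproduces the intended
  Bonferroni-equivalent familywise control, verified by the null
  calibration (median selected loci ≤ 1 over 200 null runs) and the
  power study (≥ 0.9 for planted QTL at R² ≥ 5%, ≤ 1 mean false
  positive);
- the summed marker R² is capped at the trait's heritability: a
  candidate that would push the mapped total past `h2_cap` is refused,
  which is what makes the unmapped-polygene remainder non-negative by
  construction;
- ties break on smallest P, then largest incremental SS, then genome
  order.

Allele effects are deviation-coded (sum to zero within a locus; within
each environment and across environments for interaction terms), so a
biparental marker reports `+a/−a`. Contributions are sequential
(entry-order) incremental sums of squares over the total SS; on
near-orthogonal biparental panels this agrees closely with partial R²
(a diagnostic, `sequential_vs_partial_r2`, quantifies the gap — early
entries absorb finite-sample correlation). Interaction contributions are
reported on the same total-SS scale as main effects, so all shares and
the heritability partition are commensurable. Large-contribution genes
are those at or above 1.5% of phenotypic variance (inclusive threshold).

Eigenvector covariates (top-k of the allele-sharing similarity matrix)
are available but default to k = 0: a biparental RIL panel has no
population structure to correct, and structure correction in such a panel
only costs degrees of freedom.

## Cross potentials

The free-assortment potential is exact:
`μ + Σ_l best(e_il, e_jl)` equals the genotypic value of the optimal
transgressive progeny when every locus segregates independently, and it
matches exhaustive 2^L enumeration in the tests. The linkage model is
**defined operationally** as a seeded Monte-Carlo: simulate `n_progeny`
inbred progeny of the cross by map-based single-seed descent (defaults
1000 progeny, 5 selfing rounds) and report the extreme — or a stated
quantile — in the favorable direction. This is a declared operational
definition, not a closed form; its two limits are verified exactly
(complete linkage in repulsion blocks stacking; large map distances
converge to the free-assortment bound). Missing allele effects contribute
zero (the population mean), flagged per pair. Percentiles interpolate
linearly between order statistics, and the 10th percentile is taken from
the favorable tail (small values for a smaller-is-better trait).

## Expression and networks

The DEG rule names thresholds, not a test, so the package uses a Welch
t-test on log2(FPKM + 1) across replicates with pseudocount 1, and the
fold change from group-mean FPKM with the same pseudocount — a
dependency-free, deterministic choice with the threshold applied to a
well-defined quantity. No multiple-testing correction is applied by
default (the rule is the raw per-gene P ≤ 0.05); a BH-FDR switch exists.
Counts are simulated negative-binomial with gene-wise dispersion (0 =
Poisson); FPKM is computed downstream, never simulated directly, so
library-size invariance holds by construction.

Edge lists are filtered at score ≥ 0.18 after autodetecting 0–1000
integer exports; links are unweighted degree after filtering. Key hubs
use the strict more-than-10-links rule. Chunking splits n genes into
⌈n/2000⌉ random groups whose sizes differ by at most one; top-hub
selection takes the five highest-degree nodes per group *including all
ties at rank five* (inclusion depends on degree only; node id is a
presentation tie-break).

## Problem sizes and determinism

Every generator and every stochastic procedure takes an explicit seed;
the pipeline fans one global seed into per-stage seeds via
`numpy.random.SeedSequence.spawn`, so identical config + seed gives a
byte-identical report. The test suite's simulation studies use a
246–250-line panel on a 100–200-locus genome with 3 environments × 3
replicates, 100 power runs, 200 null runs and 500 variance-component
replicates — sizes at which the Monte-Carlo error of each checked
quantity is several times smaller than its tolerance.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the analyses assume:
balanced designs, additive multi-allelic marker effects,
environment-centered interaction, NB count noise, scale-free interaction
graphs. They do not emulate field spatial trends, selection or epistasis
during line development, dominance (the lines are near-fully inbred by
design), expression outliers or batch effects, or the biological
clustering of real interaction networks. Passing tests therefore
demonstrate that the estimators and accounting are correct under their
own model assumptions — not that those assumptions hold for any
particular field experiment.

## Known limitations

- The linkage-model potential is Monte-Carlo; its value carries
  simulation error of order the progeny-score spread over √n_progeny.
- Sequential R² attribution is order-dependent in principle; only on
  (near-)orthogonal designs is it attribution-unique.
- The stepwise scan fits fixed effects only; kinship/mixed-model
  corrections are out of scope, appropriate for a biparental RIL panel
  but not for diverse germplasm.
- `anova_components` requires balance; incomplete trials need external
  pre-balancing (e.g. dropping incomplete lines) before estimation.
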