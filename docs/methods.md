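# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, and the package's known limitations.

## Panel model and content scores

A panel is a strain × marker matrix of parental-origin calls, `P1`
(reference parent, N2-like), `P2` (alternative parent, Hawaii-like) or
`MISSING`. The model is strictly biallelic-homozygous: recombinant inbred
lines are inbred for ~20 generations, so heterozygous or ambiguous calls in
input files carry no parental-origin information and are coded `MISSING` on
read. Internal genomic coordinates are 1-based inclusive (WormBase GFF
convention); BED input is shifted on read.

Per-marker minor-allele frequency is computed over non-missing calls. The
minor-allele (MA) set contains every *informative* marker — MAF neither 0
nor exactly 0.5 — paired with its minor allele; an exact 50/50 tie
identifies no minor allele and is excluded. MAC2 restricts the MA set to
markers whose MAF departs from 0.5 by a χ² goodness-of-fit test
(df = 1, no continuity correction; the statistic reduces to (2k − n)²/n for
minor count k of n). An exact binomial variant is available behind a flag.
At n = 237 the χ² rule admits minor counts up to 103 of 237 at α = 0.05.
HAC pairs every informative marker with the `P2` allele.

Scoring under missingness: a strain's denominator is the number of the
set's markers with a non-missing call *in that strain*, not the global
marker count. "Total SNPs scanned" is ambiguous once calls are missing;
the per-strain denominator is the only convention that keeps every score in
[0, 1] and comparable across strains. Numerator and denominator are both
reported for audit. A strain with no non-missing call over a set gets an
undefined (NaN) score and a flag.

## Statistical primitives

Classical tests delegate to scipy (`fisher_exact`, `ttest_ind`, `f_oneway`,
`chi2`); the test suite verifies them against independent oracles
(integer-arithmetic hypergeometric enumeration, hand sum-of-squares, the
F = t² identity). Student's t defaults to pooled variance — the classical
"Student's t-test" — with Welch behind a flag. Fisher's one-tailed variant
tests enrichment of the top-left cell.

Spearman correlation uses midranks and the t approximation
(t = ρ√((n−2)/(1−ρ²)), df = n−2) for p; for n ≤ 9 an exact p by full
permutation enumeration is available. The vectorised form (`spearman_matrix`)
ranks each row once and computes Pearson correlations of ranks by a single
matrix product; the 10,000-gene type-I calibration test shows the t
approximation holds the 5% level inside the 99% binomial band at n = 48.

FDR control: Benjamini–Hochberg via statsmodels, and Storey q-values
implemented here (no Python port of the R `qvalue` package is available):
π₀(λ) = #{p > λ}/(m(1 − λ)) on the grid 0.05…0.95 (step 0.05), smoothed by
a cubic polynomial and evaluated at the largest λ, clipped to (0, 1];
q-values are the usual step-up with enforced monotonicity. Forcing π₀ = 1
reproduces BH exactly, which the tests assert.

All stochastic procedures take an explicit integer seed; there is no global
RNG state. Permutations are drawn uniformly with replacement and the
identity permutation is not excluded; requesting more permutations than n!
simply resamples (logged).

## Expression screen

Missing expression cells are imputed from the K = 10 nearest genes
(Euclidean distance as the mean squared difference over co-observed strains;
the missing cell becomes the unweighted mean of the k nearest genes observed
in that strain). Observed values are never altered; genes with no observed
value are dropped.

The screen statistic is Spearman's ρ of each gene against the response
(MAC or trait). One coherent rank statistic supplies both the per-gene p
and the permutation q; the classic microarray d-statistic with its fudge
factor s₀ is deliberately out of scope. The permutation q-value follows the
SAM construction: for every candidate threshold t on |ρ| (the grid is the
observed |ρ| values themselves, exhaustively),

FDR(t) = π₀ · median_b #{|ρ_null,b| ≥ t} / #{|ρ_obs| ≥ t},

with the null from B response permutations (default B = 1000) and π₀
estimated as the fraction of observed statistics inside the interquartile
range of the pooled null divided by 0.5 (configurable off, π₀ = 1, for
conservatism). A gene's q is the minimum FDR over all thresholds that call
it, clipped to [0, 1]. Significance uses the dual cutoff q < 0.15 and
p < 0.05.

A known property of the median-exceedance estimator: on *fully null* data
the top-ranked gene sees a median null exceedance count of zero in roughly
half of datasets and then receives q = 0, so occasional single false calls
are expected. The calibration suite therefore tracks the false-call rate
per gene tested (≈ 0.2% of 500 null genes per screen, far below the 15%
target) and the realized false discovery proportion among candidates on
planted data, where the intersection of two screens suppresses false calls
almost entirely.

## QTL scan

Each marker is tested by OLS regression of the trait on genotype coded
{P1: 0, P2: 1}; on a binary predictor this is algebraically the pooled
two-sample t-test, and the tests assert the identity exactly. Markers
monomorphic within the joined strain set, or with fewer than three usable
strains, are reported with a skip reason. The scan's FDR defaults to Storey
q-values (BH selectable). An optional label-permutation p permutes the
*trait* across strains: inbred panel strains are treated as exchangeable,
which differs from family-structure-aware tools that permute genotype
instead; for a RIAIL panel the two designs coincide in expectation.

## Integration

Candidates are genes significant in both screens. Discordant-direction
candidates are retained and flagged rather than dropped — no exclusion rule
is defined for them, and discordance is information. The chance overlap of
two screens of sizes n_A and n_B over N genes is N·(n_A/N)·(n_B/N); the
enrichment p is the hypergeometric upper tail (one-tailed Fisher), with a
binomial variant for sensitivity analysis.

Nearest-SNP assignment minimises the unsigned distance from the nearer gene
boundary (first/stop codon); markers inside the gene interval return an
`in_gene` sentinel. The signed distance is strand-aware: positive on the
gene's 5′ side, negative on the 3′ side; equidistant ties break toward the
5′ side for determinism. Whether published distance tables are strand-aware
or genome-forward cannot be verified without coordinates; the strand-aware
convention is this package's choice and is flagged here.

Allelic effects are pooled two-sided t-tests between P2- and P1-carrier
strains at a marker, reporting group means ± SEM; a carrier group smaller
than two yields an explicit "na" result.

## Synthetic data generator

The generator emulates the statistical structure the analysis consumes, at
the published scale, with defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `n_strains` | 237 | panel size |
| `chrom_markers` | 6 chromosomes totalling 1454 | marker map (10 kb spacing) |
| `recomb_prob` | 0.02 | parental-switch probability between adjacent markers (~5 blocks/chromosome, advanced-intercross scale) |
| `skew` | 0.05 | per-marker selection skew; target P2 frequency 0.5 − skew |
| `beta_mac` | 1.0 | trait units per unit MAC |
| `noise_sd` | 0.18 | trait noise (see calibration below) |
| `n_genes` / planted | 2000, 20 pos + 10 neg | expression matrix with planted MAC-loaded genes |
| `gamma` | 1.0 | planted-gene loading on standardised MAC (expression noise SD 1) |

Genotypes: per chromosome a two-state Markov chain over markers generates
parental mosaics; selection during panel construction is then imposed
phenomenologically by flipping individual strains' alleles at each marker
with exactly the probability that moves the expected frequency to its
target (zero-skew markers are untouched, preserving drift-scale variation).
This was chosen over forward simulation with explicit fitness because the
analysis consumes only the realised frequency structure, and the
phenomenological route is controllable and fast. At skew 0.05 and n = 237
roughly a third of markers have MAF significantly below 0.5, matching the
published panel's 526/1454 proportion.

Trait: intercept + β_MAC·MAC (+ major-locus effect) + Gaussian noise. A
background-restricted major locus confines the MAC effect to P2 carriers,
emulating the npr-1-like stratification, and labels strains with an
`HW`/`N2` stratum column. `noise_sd` was calibrated by a sweep
(0.14–0.20 across 40 seeds each) so the population Spearman correlation
between MAC and trait is ≈ 0.4, the regime the method targets; the realised
correlation still varies ±0.06 across panels, so candidate recovery
fluctuates seed to seed.

Expression: planted genes are ±γ·z(MAC) plus unit Gaussian noise — they
inherit their trait correlation *through* the MAC–trait coupling, exactly
the causal structure the double screen assumes — and all other genes are
pure noise.

What the generator does **not** emulate: linkage disequilibrium between
expression and local genotype (cis-eQTL structure), probe-level artefacts,
correlated gene modules, non-Gaussian expression noise, and genetic
incompatibility between parental genomes. Passing recovery tests therefore
demonstrates the pipeline's correctness under its own assumptions, not its
power on real microarray data.

## Problem sizes used in the validation suite

The test suite and acceptance script choose sizes that make each property
decisive while staying desk-scale: exhaustive Fisher agreement over all 2×2
tables with margins ≤ 30; exact Spearman at n = 7 against all 5040
permutations; 10,000-marker/-gene type-I calibration at n = 48 strains;
50 replicate null screens of 500 genes × 48 strains at 200 permutations;
end-to-end recovery on the default 237 × 1454 panel with 30 planted genes
among 2000 (200 screen permutations); and 100–200 seeded panels for the
MAC-coefficient recovery check. The acceptance script averages the
simulated study over five replicate panels to damp seed-to-seed variation.

## Known limitations

* The permutation q-value is a point estimate; no confidence band is
  attached, and single false calls on null data are inherent to the
  median-exceedance construction (see above).
* The ped/map reader must guess which nucleotide came from which parent;
  the lexicographic default is deterministic but arbitrary — supply
  `parent_alleles` when the parental assignment is known.
* Storey's π₀ smoother uses a cubic polynomial rather than a natural
  spline; on small p-value sets the estimate is clipped rather than refit.
* The QTL scan fits one marker at a time with no kinship or interval model;
  it is a background-rate tool, not a mapping replacement.
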