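# Methods

This note documents the models, defaults and design choices behind
admixscan, and what the synthetic cohort does and does not establish about
real data.

## The statistical model of the enrichment scan

A locus window contributes one observation per haplotype: the ancestry of
the local-ancestry segment covering the window midpoint. With N diploid
individuals an autosomal locus has up to n = 2N chromosomes; an X locus has
up to 2·(#females) + (#males), because males are hemizygous. Haplotypes with
no covering segment are dropped from that locus's n — missing local-ancestry
coverage is propagated, never imputed, so every locus carries its own
denominator.

Under neutral assortment the count vector (x_AFR, x_NAM, x_EUR) at a locus
is modelled as trinomial with the population-average proportions, which are
re-estimated by pooling the same local-ancestry calls being scanned
(p̂_k = Σ x_k / Σ n). Using the calls' own pooled average rather than a
genotype-based estimate keeps observed and expected internally consistent
under one caller.

Two per-locus scores are always reported side by side:

- **pmf** — the trinomial point probability of the observed combination.
  This is the classical score for this style of scan and what a Manhattan
  plot of the analysis shows; it is *not* a calibrated P-value (it never
  reaches 1, and its null distribution shifts with n).
- **exact tail** — the exact multinomial test: the sum of probabilities of
  all compositions of n whose pmf does not exceed the observed pmf
  (point-probability ordering). This is a proper, conservative-by-discreteness
  P-value and the default basis for the significance flag and for
  Benjamini–Hochberg q-values. Enumeration over the (n+1)(n+2)/2
  compositions is done once per distinct n and cached, with ties resolved in
  log space at a relative 1e-9 tolerance.

The significance threshold defaults to P < 1e-9 on the chosen score, the
stringency used for gene-level follow-up in this kind of scan. BH q-values
are computed over the m loci with n > 0. Log-fold enrichment is
log2(x_k / (n·p̂_k)); a zero count is reported as −inf (an exact depletion),
left as a sentinel in tables and floored only for plotting. Runs of
consecutive scanned loci on one chromosome that are significant with the
same top enriched ancestry merge into reportable segments (carrying the
minimum tail P and pmf), which are then intersected with gene intervals
under strict half-open overlap (≥1 bp; abutting does not count).

Caveat for pedigree-structured data: chromosomes sampled from a finite
recently-admixed population are positively correlated through shared
founders (IBD), which overdisperses locus counts relative to the trinomial.
The type-I guarantee in the acceptance suite is for the trinomial null
itself; on simulated whole cohorts a handful of loci can exceed even the
1e-9 threshold without selection. Real analyses should read the scan as a
ranking with an FDR summary, not as an exact error rate — the same caution
applies to any scan of this design.

## Global ancestry

**Tract route.** Per ancestry, covered length with that ancestry divided by
total covered length, separately over autosomes, X, and their union.
`F_total` includes X by default (a flag drops it), with the natural length
weighting: males contribute one X copy, females two.

**Genotype route.** Supervised admixture estimation with the three reference
allele-frequency vectors fixed: per individual, EM maximises
Π_m Binomial(g_m | ploidy_m, Σ_k q_k f_mk) over the 3-simplex.
Supervision (rather than unsupervised k=3 estimation) makes the fit
deterministic and desk-scale; frequencies are clipped to [1e-6, 1−1e-6];
initialisation is the uniform simplex point so ties (e.g. identical
frequencies across populations, where the likelihood is flat) resolve to the
uniform answer rather than to a random one. The log-likelihood is
non-decreasing by construction and is asserted in tests. Stopping: every
individual's log-likelihood improves by less than `tol` (default 1e-3) or
`max_iter` (default 1000, a warning not an error); the proportions are
stable to better than 1e-3 well before the likelihood plateaus. Males on X
enter with ploidy 1.

**Distances and PCA.** The allele-sharing distance is the mean over shared
non-missing SNPs of |g_i/p_i − g_j/p_j| — the fraction of allelic
differences (0 for identical calls, 1 for opposite homozygotes, 1/2 for
het-vs-hom). It is not guaranteed to be a metric (triangle inequality is not
asserted). PCA standardises the distance-matrix columns (centred, unit
variance, ddof 1) before decomposition — a scaled PCA of the matrix — with
zero-variance columns zeroed.

## Sex-biased admixture

ΔAdmix = (F_X − F_auto)/F_total per ancestry; positive means maternal
(female-lineage) excess. Cohort-level fractions are pooled covered-length
weighted means over individuals rather than means of per-individual ratios:
the ratio is unstable for individuals nearly lacking an ancestry, while the
pooled version degrades gracefully (the per-individual-mean alternative is
available via a flag). Records are canonicalised by individual id, so the
statistic is exactly order-invariant.

Uncertainty: percentile bootstrap over individuals (default 1000
replicates, 95% interval). Replicates in which the ancestry is entirely
absent are redrawn (capped at 10× the replicate count). Two-sided P-values
use 2·min(Pr(· ≤ 0), Pr(· ≥ 0)) with the (k+1)/(B+1) add-one correction, so
no reported P can fall below 2/(B+1) — resampling P-values smaller than that
floor are not obtainable from a 1000-replicate bootstrap, which is why this
package reports the floor rather than extrapolated tail probabilities. Each
cohort's resampling stream is keyed by a CRC32 of its sorted individual ids
combined with the user seed, which makes two-cohort comparisons exactly
symmetric in their arguments.

Detectability at realistic effect sizes: with founding proportions
constrained to average 7.3/18.1/74.6, the European ΔAdmix is bounded near
−0.05 (F_X converges to (2·maternal + paternal)/3 of the founding split), an
effect a 60-individual cohort resolves only marginally — single seeded runs
can show CIs covering zero for EUR and even a sign flip for NAM. The
direction and CI-exclusion properties are therefore validated under a
decisively sex-separated founding (fathers 5/0/95, mothers 0/85/15 percent
AFR/NAM/EUR) with 120 sampled individuals, where the asymmetry is resolved
in essentially every replicate.

## The synthetic cohort

What it emulates: a small cohort of three-way admixed diploid genomes with
strongly sex-biased founding (European-paternal, Native-American-maternal),
recombination-broken ancestry tracts on six autosomes plus X (~0.87 Gb
total, 0-based half-open coordinates), and genotypes at
ancestry-informative SNPs.

- **Founders** are unadmixed; each chromosome copy is one full-length tract
  whose ancestry is drawn per haplotype from the founder proportions of the
  founder's sex. Defaults: males (0.100, 0.050, 0.850), females
  (0.046, 0.312, 0.642) — sex-averaging to the 7.3/18.1/74.6 cohort means
  the simulation targets, with paternal excess for both AFR and EUR and
  maternal excess for NAM.
- **Mating**: non-overlapping generations (default 6 — admixture depth is a
  free parameter, not an inference target), random father and mother per
  child, no selfing (parents are of different sexes by construction),
  constant breeding-population size (default 500). The emitted cohort is a
  random sample of `n_individuals` (default 60) from the final generation:
  a cohort-sized breeding population would put pedigree drift far above the
  sampling variance a bootstrap over individuals measures, which matches no
  real study design. The simulator also records the realized ancestry pool
  of the entire final generation — the population parameter that
  bootstrap-coverage studies check against.
- **Recombination**: crossover count per transmission is
  Poisson(length × rate / 1e8) with uniform breakpoints (default rate 1
  crossover per 100 Mb ≈ 1 cM/Mb, uniform; no hotspot map — the scan
  operates on windows, not hotspot structure). The male X is transmitted
  intact and only to daughters; sons receive the maternal X only, stored as
  haplotype index 0, so X locus counts are 2·females + males with no
  special-casing downstream.
- **Genotypes**: Balding–Nichols frequencies per SNP — base frequency
  uniform on (0.05, 0.95), population frequencies Beta(p(1−F)/F,
  (1−p)(1−F)/F) with F = 0.15 by default (continental-scale divergence,
  Var = F·p(1−p)); each haplotype's allele is Bernoulli in the frequency of
  the ancestry covering the position; male X dosages are hemizygous {0,1}.
- **Determinism**: one master seed feeds named, order-stable substreams
  (frequencies, positions, pedigree, genotypes); a fixed seed reproduces
  every output file byte for byte.

What it does not emulate — and hence what passing tests do not show about
real data: no coalescent history within the ancestral populations (reference
panels are exact frequency vectors, so supervised estimation faces no panel
misspecification), no LD beyond that induced by ancestry tracts, no
genotyping error or phasing/local-ancestry-caller error (segment labels are
exact truth), no mutation, no selection, no hotspot structure, and uniform
window sizes rather than recombination-map loci. Results on real data will
additionally reflect caller error and reference-panel mismatch, which this
pipeline treats as upstream concerns.

## Problem sizes used in the automated checks

Acceptance-scale runs are sized for a single CPU: the cohort at the default
60 individuals (population 500) with ~10,500 SNPs for EM recovery checks;
20 replicate cohorts for tract-based recovery and for sex-bias direction;
200 replicate cohorts on a reduced three-chromosome genome for bootstrap
coverage; 10,000-locus count matrices at n = 120 for the scan's calibration
and power checks; and one-million-draw Monte-Carlo cross-checks of the
exact multinomial tail. Cohort-mean recovery is asserted on the average
over replicate cohorts, since a single finite cohort's mean carries founder
sampling and drift noise of the same order as the tolerance.

## Numerical and interface choices

- All pmf work is in log space via log-gamma; p_k = 0 with x_k > 0 yields
  exactly zero probability.
- The trinomial implementation is cross-checked in tests against an
  independent route (scipy's multinomial log-pmf) and the exact tail against
  full hand enumeration and Monte-Carlo; BH q-values are cross-checked
  against a hand-rolled step-up.
- The combination-frequency grid is exact over (x_AFR, x_NAM) when all loci
  share one n; with heterogeneous n it bins proportions x/n on a fixed grid
  (default resolution max(n)+1), documented in the output header.
- VCF is the only genotype dialect (1-based POS converted at the boundary;
  all internal coordinates are 0-based half-open BED convention);
  multiallelic records are skipped with a logged count; missing GT is
  missing, never zero. Haploid calls round-trip as written.
- Ancestry labels are the closed alphabet {AFR, NAM, EUR}; the YRI/CHB/CEU
  reference surrogates are translated at the file boundary, and a label map
  hook accepts other callers' labels.
- The CLI mirrors the pipeline stages; a YAML config file can override any
  flag (file wins over flag). A JSON manifest with parameters, seed and
  SHA-256 checksums of inputs and outputs is written for every run,
  including failed ones (with the failing stage recorded).

## Known limitations

- The exact-tail enumeration is O(n²) per distinct n and capped at
  n = 10,000 chromosomes.
- The scan's trinomial null ignores between-chromosome IBD correlation (see
  above); a permutation or pedigree-aware null would be the next step.
- Percentile bootstrap intervals (not BCa); at n = 60 their realized
  coverage in simulation is a few points below nominal, within the accepted
  90–99% band.
- The unsupervised k=3 admixture objective, LD pruning, mtDNA/Y haplogroup
  analysis and pathway enrichment are out of scope.
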