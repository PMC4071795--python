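# Methods

This note documents the models, estimators, numerical conventions and
simulator design behind `meiomap`, including the choices made where more
than one defensible option existed.

## Crossover detection

**Informative markers and match profiles.** Only sites where the sire is
heterozygous and fully phased identify which sire haplotype an offspring
received. For each (pair, chromosome) a match profile records, at every
informative marker, whether the putative paternally inherited offspring
haplotype carries the allele of sire haplotype 1 or 2. A crossover is a
change of that label between consecutive informative markers; the event is
localized to the interval between them, whose length `r_k` (Mb) is carried
into the window-rate estimator. Crossovers falling inside the same
inter-informative gap cancel pairwise (only the parity of the gap count is
visible), which is the fundamental resolution limit of the approach — the
test suite's "parity oracle" encodes exactly this.

**Paternal-haplotype assignment.** A truly paternal haplotype can never be
an impossible transmission: at any site where the sire is homozygous it must
carry that allele. The assignment therefore ranks the two offspring
haplotypes primarily by their conflict rate with the sire genotype
(fraction of non-missing sites with an opposite-homozygote impossibility)
and only breaks exact ties by total identity against the closer single sire
haplotype, then deterministically to haplotype 0 (logged). A pure
identity-based rule misassigns whenever the dam happens to carry a
haplotype similar to one of the sire's — common in populations with shared
ancestry — whereas the conflict criterion is invariant to how many
crossovers the gamete contains.

**Filter cascade.** Five filters run in fixed order, each flagging (never
deleting) events with a single primary reason:

1. `double_lt2Mb` — both members of consecutive event pairs whose
   between-event tract spans < 2 Mb (phase-switch and gene-conversion
   signature). Chains of close events are removed wholesale.
2. `gt3_per_chrom` — all events of a (pair, chromosome) with > 3 events
   remaining after step 1.
3. `pair_mismatch` — all events of pairs whose genome-wide haplotype
   mismatch (conflict) rate exceeds 0.05.
4. `hot_window_excess` — events overlapping windows whose *provisional*
   rate (from unfiltered events — a two-pass scheme, since the filters
   reference rates that depend on events) is significantly above 0.025 by
   a one-sided exact binomial test at α = 0.05, with `round(c_w·T)`
   successes out of `T` meioses. The null rate, the test and α are
   configurable; an exact test was chosen because window event counts are
   small integers.
5. `snp_mismatch` — events overlapping windows containing a SNP whose
   across-pairs conflict rate exceeds 0.05 (marker-placement errors).

Both members of a close double are removed (the tract between the two
phase switches is the physical double-crossover segment); the `>3` rule
removes the chromosome's events but keeps the pair. Filtering
systematically *attenuates* GRN: the `gt3` and `double` rules preferentially
fire for high-recombination sires, so downstream genetic-length and
heritability estimates from filtered data are biased slightly downward —
the cost of robustness to phasing artefacts, and visible in the package's
own recovery experiments (below).

## Recombination statistics

**Binomial (truncated) crossover model.** Counts per chromosome follow
`Binomial(N, x/N)` with `x` = length in Morgan (100 Mb = 1 M) and `N = 4`;
`Σ t·p(t) = x` holds identically, which doubles as a numerical invariant.
The companion map function `r(x) = (1 − (1 − 2x/N)^N)/2` lies between
Haldane's `(1 − e^{−2x})/2` and Kosambi's `tanh(2x)/2` on (0, 0.8] M,
checked on a grid.

**Genetic length.** Estimated as 100 × mean retained crossovers per meiosis
per chromosome; genome totals are sums and the genome cM/Mb is the ratio of
sums. This estimator is consistent with a GRN-based genome total; with
filtering it underestimates the expected binomial length.

**Window rates.** Each event distributes unit mass over the 1 Mb windows
its interval overlaps, proportional to overlap (`x_k/r_k`), divided by the
number of meioses. Intervals are integer-bp, half-open `[left, right)`;
window `w` covers bp `[w·10⁶, (w+1)·10⁶)`, so the window of bp `b` is
`b // 10⁶` and the attribution matches a per-bp integration oracle exactly
(mass conserved to 1e-9). Terminal partial windows absorb their share.
Hot/cold thresholds (0.02 / 0.004 per meiosis) are fixed constants,
configurable.

**Window haplotype counts.** Distinct haplotype strings per window over all
2n haplotypes; haplotypes with frequency strictly below the 5th percentile
of the window's haplotype-frequency distribution are dropped (phasing-error
suppression), ties at the threshold kept. A literal 5%-frequency floor is
available as an option but caps counts at 20, which is inconsistent with
realistic window haplotype diversity. Group (hot/cold) comparisons adjust
for SNP number per window by single-covariate least squares on window
counts, re-centred at the grand mean.

## Genetic models

**Repeatability model.** `y = 1μ + Zu + Zp + e` with `Var(u) = A σ²_a`
(numerator relationship matrix among sires by the tabular method, unknown
parents as unrelated founders), sire-level permanent environment `p`, and
per-record residuals. A Gibbs sampler updates μ, `u` (joint multivariate
normal via a Cholesky solve), `p` (independent per sire), and the three
variances with scaled-inverse-chi-square conditionals. Priors are ν = 4
with scales set so each variance's *prior mean* equals one third of the
phenotypic variance — symmetric and weakly informative. h² and
repeatability are posterior means of per-sample ratios; effective sample
sizes come from an initial-positive-sequence autocorrelation estimator.
Identifiability caveat: with unrelated sires, σ²_a and σ²_p are confounded
(only their sum is likelihood-identified); separation requires relatives
among the phenotyped sires, which the simulator provides (below).

**Residual weights.** Sire-mean phenotypes are weighted by
`w_n = (1−h²)/(c·h² + (1+(n−1)t)/n − h²)` with `c = 0.40` by default (the
proportion of genetic variance not captured by markers); residual variance
of sire i is modeled as `σ²_e / w_i`.

**BayesB/BayesC.** Single-site Gibbs sampling (numba-compiled; bit-for-bit
reproducible under a fixed seed, single-threaded) of
`y_i = μ + Σ_j z_ij s_j + e_i` with the spike-and-slab prior
`s_j ~ N(0, σ²_{s,j})` w.p. 1−π and `s_j = 0` w.p. π; locus-specific
variances with scaled-inverse-chi-square priors (BayesB, excluded loci
refresh their variance from the prior) or a common variance (BayesC).
Genotypes are centered, not standardized. The SNP-variance prior scale
spreads an assumed genetic proportion (default 0.5) of the phenotypic
variance over the *total* genotypic variance of all markers. This keeps the
prior weak relative to the likelihood: on a signal-free phenotype the
per-iteration included fraction sits at the prior rate 1−π (the posterior
mean inclusion is always ≤ 1−π — Jensen's inequality applied to the
saturating posterior-odds function — and the gap grows with prior
concentration; the alternative convention concentrating the variance into
the expected (1−π)k included SNPs is available as
`prior_spread="included"`). Heavy scaled-inverse-chi-square tails still let
locus variances grow to capture major QTL: a planted QTL explaining 20% of
phenotypic variance reaches posterior inclusion ~1 and its window the
genome-maximum variance share.

Per post-burn-in sample, genetic variance is the variance across
individuals of the genomic values `Zs`; each window's variance is the
variance of its partial sums, its percentage ignores between-window
covariance (sample-wise denominators), and WPPA is the fraction of samples
with ≥ 1 included SNP in the window. Candidate-SNP variance shares are
posterior-mean drops of the window's share when that SNP's contribution is
removed, accumulated during sampling. Marker h² uses the mean residual
variance `σ²_e · mean(1/w_i)`.

**QTL calling, Me, single-SNP test.** Candidate windows need ≥ 0.2%
genetic variance AND WPPA ≥ 1.5 × the genome mean; reported with ±2 Mb
flanks and a candidate SNP (argmax PPI; ties → larger variance share, then
lowest bp). `Me = 2·Ne·L·k/ln(Ne·L)` uses the natural log (convention of
the effective-segment literature); single-SNP confirmation is a GLS F-test
with covariance `σ²_a A + σ²_e I` and the SNP as a class factor, which
reduces exactly to one-way ANOVA when `A = I`.

## Imputation evaluation

Cross-validation folds come from K-means (k-means++ init, 50 restarts,
seeded) on rows of the relationship matrix — raw rows, no whitening. The
internal imputer is deliberately naive: for each unobserved marker of each
target haplotype it copies the allele of the reference haplotype with the
fewest mismatches at observed markers within a sliding window (default
1 Mb; ties → more frequent reference haplotype, then lowest index in the
deduplicated lexicographic order). It exists so the
simulate → mask → impute → evaluate loop runs with no external tool, and it
degrades near crossovers precisely because one local donor cannot span a
template switch — the mechanism relating accuracy to recombination. It is
not an HMM and its absolute accuracies are below what production imputation
achieves at equal panel density; only relative/directional statements
should be read from it. Window mismatch counting uses the binary identity
`Σ|t−r| = Σt + Σr − 2·t·r` (one small matrix product per distinct window);
missing alleles enter as 0.5, adding a donor-independent constant that
leaves the argmin unchanged. Accuracy is the identity fraction over masked
entries only, aggregated per marker/animal/chromosome/window (the genome
value is the mask-weighted chromosome mean by construction); adjacent-SNP
r² is the squared genotype correlation of physically adjacent pairs,
boundary-straddling pairs assigned to the left SNP's window.

## Simulator

The generator emulates a half-sib beef-cattle SNP-array design:

- **Marker maps** — ~1 SNP per 61 kb (configurable), random positions per
  chromosome.
- **LD** — founder haplotypes are mosaics of a small ancestral template
  pool (default 4 templates, mean segment 1.0 Mb, per-site mutation 0.002).
  These defaults were calibrated so mean adjacent-SNP r² ≈ 0.19–0.21 at
  61 kb spacing — the level reported for real 50K bovine data (~0.24) —
  while LD decays over ~1 Mb so that association signals localize to their
  window. Whole-template founders (`founder_segment_mb=None`) give
  non-decaying chromosome-scale LD; the imputation-direction experiments
  use that mode, where donor haplotypes are identifiable and the accuracy
  deficit is attributable to fresh meiotic crossovers rather than to
  historical template switches the naive imputer cannot follow.
- **Meiosis** — crossover counts `Binomial(N, m·x/N)` per chromosome
  (`N = 4`; error raised if `m·x/N > 1`), positions drawn by window weights
  (uniform, or hot windows with a configurable multiplier) then uniformly
  within the window; no interference; starting haplotype a fair coin.
- **Heritable recombination phenotype** — each sire's expected-GRN
  multiplier is `exp(g_i)` with `g_i` *genomic*: planted QTL effects
  (`qtl_spec`, per-allele effects in GRN units) plus many small background
  SNP effects, jointly scaled so the between-sire variance of expected GRN
  against the binomial within-sire variance yields the target `grn_h2`
  (`σ²_g = h²/(1−h²) · W / X²` on the log scale, with `X` the genome length
  in Morgan and `W` the summed binomial variances). Genomic rather than
  drawn-from-the-pedigree values make genetic resemblance follow haplotype
  inheritance automatically, so both the pedigree- and the marker-based
  estimators see the same signal.
- **Sire pedigree** — with `n_grandsires > 0` the first sires are founders
  and every later sire is the son of a uniformly chosen earlier sire,
  giving a deep multi-generation bull pedigree dense in 0.5/0.25/0.125
  relationships. This is what makes σ²_a separable from σ²_p: measured by
  maximum likelihood on matched designs, the deep pedigree recovers
  h² = 0.25 ± 0.02 across seeds at 300 sires where a single grandsire
  generation gives 0.23 ± 0.05.
- **Error processes**, applied in the fixed order conversion → genotyping →
  switch, all recorded in truth tables: gene conversion replaces a
  geometric tract (mean 2 kb) on the gamete with the homologous sequence
  (tract count Poisson per gamete); genotyping errors flip a call to a
  uniformly chosen different code; switch errors swap haplotype labels from
  a heterozygous site onward (an involution). A single switch in an
  offspring makes the putative paternal haplotype a paternal/maternal
  chimera — beyond the switch, match labels are noise — so realistic
  per-het-site switch rates are small (10⁻⁵–10⁻⁴); the filter cascade is
  what contains the damage, and the suite verifies that filtering brings
  GRN closer to truth under switch errors in ≥ 18/20 seeds.

All randomness flows from one seeded `numpy.random.Generator`; identical
configs give byte-identical outputs.

What the simulator does *not* model: coalescent-realistic allele-frequency
spectra and LD, crossover interference (a gamma-renewal process is out of
scope by design), sex-specific maps, the X chromosome, genotyping-batch
structure, and maternal-side meioses (dams are ungenotyped founders, as in
the paternal half-sib design). Passing recovery tests therefore demonstrates
internal consistency of the estimators under the stated generative
assumptions, not performance on real data.

## Problem sizes and experiment conditions

The recovery experiments run at sizes chosen for a single CPU: end-to-end
GRN recovery at 200 sires × 10 offspring on 5 × 100 Mb chromosomes
(error-free), the filter-benefit and imputation-direction experiments at
50–100 sires over 20 seeds each, GWAS calibration at 150–200 individuals ×
5200 SNPs over 2600 windows, and heritability recovery at 300 sires × 10
offspring with the deep sire pedigree (30 founder sires). Heritability
recovery is assessed on the simulator's true per-gamete crossover counts —
parameter recovery of the sampler itself; the same fit on detected GRN runs
about 0.05 lower because of the filter attenuation discussed above.

## Known limitations

- The repeatability-model posterior mean of h² carries a mild downward
  pull along the weakly identified σ²_a/σ²_p ridge even with the deep
  pedigree (~0.20 posterior mean at a true 0.26 at these sizes).
- Window variance percentages ignore between-window covariance; with
  strong inter-window LD the shares of adjacent windows are not additive.
- The exact binomial window filter treats the fractional event mass
  `c_w·T` as a rounded count.
- The naive imputer's tie-breaking by haplotype frequency makes its output
  depend on reference-panel composition; with few observed markers per
  window its donor choice is near-arbitrary (documented in its docstring).
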