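# meiomap

Meiotic recombination analysis from phased sire/offspring SNP-array data.

In cattle (and other livestock) breeding designs, a sire with many genotyped
offspring transmits one recombined gamete to each of them. Comparing the two
phased haplotypes an offspring carries with the two haplotypes of its sire
reveals, at every *informative* marker (sire heterozygous), which sire
haplotype was transmitted; a change of matched haplotype between consecutive
informative markers is a paternal crossover, localized to the interval
between them. `meiomap` implements this detection together with everything
around it:

- **QC** — call-rate, MAF, Hardy–Weinberg and Mendelian-inconsistency
  filters for sire/offspring pairs and markers.
- **Crossover detection and filtering** — phase-change detection on
  informative-marker match profiles, plus the artefact-filter cascade
  (tight double crossovers < 2 Mb apart, > 3 events per chromosome, pairs
  with haplotype mismatch rate > 0.05, windows with recombination rate
  significantly above 0.025, windows containing high-mismatch SNPs).
- **Recombination statistics** — the genome-wide recombination number (GRN)
  per pair; observed crossover-count probabilities against the binomial
  (Karlin) model `P(t) = C(N,t) (x/N)^t (1−x/N)^{N−t}` with `x` the
  chromosome length in Morgan (100 Mb ≈ 1 M) and `N = 4` the maximum
  crossover number; genetic lengths and cM/Mb; fractional per-1 Mb-window
  recombination rates `c_w = Σ_k (x_k/r_k)/T` with hot (≥ 0.02) and cold
  (≤ 0.004) window classification; Haldane/Kosambi/binomial map functions.
- **Genetic analysis of GRN** — pedigree numerator relationship matrix
  (tabular method), a Gibbs sampler for the repeatability model
  `y = 1μ + Zu + Zp + e` (heritability and repeatability of GRN),
  family-size residual weights `w_n = (1−h²)/(c·h² + (1+(n−1)t)/n − h²)`,
  BayesB/BayesC whole-genome regression with per-window genetic-variance
  percentages and window posterior probabilities of association (WPPA), QTL
  calling, the effective-segments correction `Me = 2·Ne·L·k / ln(Ne·L)`,
  and a GLS single-SNP confirmation test.
- **Imputation evaluation** — relationship-based K-means cross-validation
  folds, a naive nearest-haplotype imputer for end-to-end testing,
  identity-fraction accuracy per marker/animal/chromosome/window,
  adjacent-SNP r² as LD, and the accuracy-versus-recombination relation.
- **Simulator** (`meiomap.simdata`) — pedigreed, phased, multi-chromosome
  genotypes with truncated-binomial crossovers placed by hot/cold window
  weights, gene conversion, genotyping and phase-switch errors, and a
  heritable, optionally QTL-driven sire recombination phenotype — with full
  truth tables, so every stage above is testable against ground truth.

## Worked example

```python
from meiomap.simdata import SimConfig, simulate_population
from meiomap import qc, xover, recstats

cfg = SimConfig(n_chromosomes=3, chrom_lengths_mb=(100.0, 80.0, 60.0),
                n_sires=60, offspring_per_sire=5, switch_error_rate=2e-5,
                seed=1)
data, pedigree, truth = simulate_population(cfg)
data, pedigree, report = qc.apply_qc(data, pedigree)

events, profiles = xover.detect_all(data, pedigree)
pairs = pedigree[pedigree["analysis_pair"]]
flagged = xover.filter_events(events, profiles, len(pairs))
grn = xover.compute_grn(flagged, pedigree)
summary = recstats.chromosome_summary(
    flagged, pedigree, dict(zip(cfg.chromosomes, cfg.chrom_lengths_mb)))
```

prints (via the surrounding report statements):

```
after QC: 2605 SNPs, 300 GRN-eligible pairs
926 events detected, 707 retained (750 true crossovers, 7 switch errors)
mean GRN = 2.36 over 300 pairs (expected 2.4)
chrom  physical_mb  genetic_cm  expected_cm  cm_per_mb
    1        100.0       93.00        100.0       0.93
    2         80.0       79.33        80.0        0.99
    3         60.0       63.33        60.0        1.06
Total        240.0      235.67       240.0        0.98
8 hot / 22 cold windows of 240
```

A 240 Mb genome is 2.4 Morgan, so each pair carries ~2.4 crossovers on
average; the detected mean GRN of 2.36 sits just below it because the
filter cascade deliberately discards ambiguous events, and the estimated
genetic lengths (100 × mean crossovers per meiosis) track the simulated
Morgan lengths chromosome by chromosome. The same stages are available as
CLI subcommands (`meiomap simulate / qc / detect / stats / gwas /
impute-eval`) operating on phased VCF + TSV files.

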