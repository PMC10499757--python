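# Methods

This note documents the statistical model implemented by `pileuplr`, the
numerical conventions, what the synthetic-data generator does and does not
emulate, and the design choices made where more than one reasonable
convention exists.

## Model

### Read-error model

A single global error rate α ∈ [0, 1) governs every read: a base is
reported correctly with probability 1 − α and as any particular one of the
other K − 1 categories with probability α/(K − 1). Symmetry across
categories is assumed throughout (appropriate for data where
damage-specific substitution patterns have been removed upstream by
UDG treatment and base-quality recalibration; an asymmetric matrix is out
of scope). Two derived quantities:

- **Error-adjusted frequencies** (simulation side): a read from a random
  chromosome shows category *i* with probability
  `f_i (1 − α) + (1 − f_i) α/(K−1)`.
- **Genotype read probabilities** (likelihood side): homozygote *a/a*
  emits *a* with 1 − α, others α/(K−1); heterozygote *a/b* emits each
  carried allele with `½(1 − α) + ½·α/(K−1)` (= ½ − α/3 at K = 4).

These are mutually consistent: the HWE-weighted mixture of genotype read
probabilities equals the error-adjusted frequencies. This identity is
property-tested, tying the simulator's null model to the likelihood
engine analytically.

### Locus likelihood

For one locus with frequencies **f** and per-individual read vectors
**r**ᵢ, the likelihood marginalizes over diploid genotypes with HWE priors
(f_a², 2 f_a f_b). Individuals are conditionally independent given **f**,
so the joint sum over all G^N genotype assignments factorizes exactly into
a product of per-individual sums over G = K(K+1)/2 genotypes. The
factorized form is the production engine; the literal joint enumeration is
kept in the test suite as a brute-force oracle and agreement is exact
(1e-12 relative) on random instances.

Conventions:

- The multinomial coefficient is included (it is the pmf); it cancels in
  every likelihood ratio, so LRs are insensitive to this choice.
- A zero-depth cell contributes likelihood exactly 1 (enforced exactly,
  not just to rounding).
- Categories with zero observed reads may be pooled into one "other"
  category (probability = sum of members); the pooled pmf is identical
  because zero counts contribute unit factors. The package exposes this
  collapsed path and tests its exactness for every genotype; the
  production engine does not need it for speed.
- All accumulation is in log space with log-gamma factorials. For α > 0
  every genotype read probability is positive, so the log-likelihood is
  finite and continuous in α; at α = 0 a pileup that no genotype can emit
  has probability exactly zero, which raises a diagnostic error naming the
  locus unless the caller opts into −∞ (as the α-profiling code does, so
  α = 0 can compete and lose honestly).

### Population frequency uncertainty

Chromosome tallies **c** (e.g. gnomAD exome+genome sums) enter either as

- **point** frequencies: the Dirichlet posterior mean (c_i + 1)/(Σc + K)
  under a uniform prior, or
- **dirichlet_sample**: one fresh Dirichlet(**c** + 1) draw per locus per
  evaluation.

The +1 prior keeps alleles unseen in the reference database possible,
which matters at founder loci where the background population's tally for
the pathogenic allele is often 0.

### Two-model comparison

Each candidate population model carries its own α. The profile samples
n (default 5,000) pairs of (α ~ Uniform[0, 0.015], per-locus Dirichlet
frequencies) per model; α̂ is the α of the best draw and the overall LR is
the ratio of the sampled maxima. Sampling is independent between models by
default (`paired=True` shares each draw's α). Per-locus LRs are reported
at each model's own α̂ with point frequencies — a deterministic convention
given the profile; the point/dirichlet alternatives remain selectable
through `cohort_loglikelihood`. Ties in α̂ break toward the smallest α.
`ml_error_rate` offers a deterministic grid profile (default 31 points;
the recovery harness uses 61, i.e. 0.00025 steps, so grid discretization
is negligible next to statistical error); an estimate at either end of the
range, or a flat profile (no reads), sets a boundary flag.

No genotype calls are ever emitted, and relatedness among individuals is
deliberately not modeled: the private-allele audit shows, per locus,
whether pathogenic reads sit in exactly one individual ("private"), in
which case relatedness cannot affect that locus's LR contribution.

### Disease-read statistic and its null

The test statistic is the number of panel loci with ≥ 1 pathogenic-allele
read across all individuals (a locus counts once however many individuals
or reads hit it). Null datasets follow a three-stage recipe per locus:
Dirichlet(counts + 1) frequency draw (fresh per simulated dataset per
locus), α-adjustment, then a multinomial read draw with the observed depth
as trials. Because all individuals at a locus share the same adjusted
probabilities within a dataset, the pathogenic-category total at a locus
is Binomial(total locus depth, p_pathogenic) — an exact marginalization
used to vectorize the null simulation; full per-individual cohorts are
available via `simulate_cohort` and the two routes' statistic
distributions are verified to agree. The grid experiment runs a total
budget of simulations (default 22,500 per population) split evenly across
a 15-point α grid on [0, 1.5%]; the empirical one-tail p is the plain
fraction of simulated statistics ≥ observed (an (r+1)/(n+1)-corrected
variant is available behind a flag).

## Synthetic data

The generator emulates the statistical structure of a founder-population
study, not sequence-level reality (no reads/FASTQ, no linkage, no
contamination, no damage patterns):

- **Panel**: biallelic loci with target pathogenic frequencies
  f_A ~ U(0.002, 0.02) (founder-effect scale) and f_B ~ U(0, 0.002)
  (background), realized as binomial tallies at 10,000 / 120,000
  chromosomes. A tally pair is redrawn if sampling noise reverses the
  ordering, so generated panels pass the strict retention filter (keep
  loci with pathogenic frequency strictly higher in A) by construction.
  An `enrichment=1` mode builds exact frequency ties — useful for testing
  that the strict filter drops them.
- **Cohort**: genotype-first — per (individual, locus), two alleles drawn
  iid from the population frequencies (HWE), a depth from the depth model,
  then a multinomial read draw through the genotype's error probabilities.
- **Depth model**: zero-inflated negative binomial. Defaults: NB means
  (20, 8, 4, 2, 1, 0.2) reads/locus across six individuals, dispersion 2,
  zero-inflation 0.15, chosen so a 159-locus six-person cohort has ~4.8k
  reads, ~39% zero-depth cells, and per-individual means spanning ~0.2–17
  — the information-sparsity regime the likelihood must handle.
- Every cohort is reproducible byte-identically from the recorded seed.

### A deliberate model mismatch, and what passing tests show

The null simulator draws reads multinomially from population-level
frequencies, ignoring that real (and generated) cohorts carry reads
clumped within carrier individuals. Genotype clumping lowers the number
of distinct loci reached by pathogenic reads, so genotype-first cohorts
score *conservatively* high tail-ps against the multinomial null (measured
mean tail-p ≈ 1.0 under the generating model at the default conditions).
Tail-p calibration is therefore assessed the only way it is well-posed:
with the observed draw taken from the evaluated model itself
(`calibration_experiment`), where the p-values are approximately uniform
(KS check). The recovery harness still records genotype-first tail-ps as
conservatism diagnostics. Passing calibration shows the empirical-p
machinery is correct; it does not certify the multinomial null as a model
of carrier clumping — users comparing real cohorts should read high
tail-ps under the "right" population as expected behavior, exactly as the
likelihood analysis (which models genotypes properly) is the primary
inference.

The likelihood comparison, by contrast, models genotypes correctly, and
the recovery experiment scores it end to end at the study-matched
conditions (159 loci, 6 individuals, α* = 0.009): error-rate recovery
(α̂ within [⅔, 4⁄3]·α*, i.e. [0.006, 0.012], in ~97–98% of replicates;
statistical error is dominated by the ~40 expected error reads, giving
SE(α̂) ≈ α/√40 ≈ 0.0014), model-selection power (LR favors the generating
population in ~96–99% of replicates depending on the realized panel; the
rare failures are cohorts that happen to carry almost no pathogenic
alleles, where the many reference-only loci legitimately tilt slightly
toward the low-frequency model), and calibration as above.

## Using real data

The bundled panel and counts are synthetic stand-ins (filenames say so).
To run on real inputs: export per-locus chromosome counts per population
(for gnomAD, sum exome and genome allele counts per nucleotide) into the
counts TSV dialect (`locus_id`, `A`, `C`, `G`, `T`), build the panel TSV
(`locus_id`, `chrom`, `pos`, `ref`, `alt`, `pathogenic_allele`,
`condition`; a VCF of variant definitions can seed it via
`read_panel_vcf`), and tabulate per-individual pileups (e.g. from
`samtools mpileup`) as `individual_id`, `locus_id`, `A`, `C`, `G`, `T`.
Unlisted (individual, locus) cells are zero-depth, not errors.

## Problem sizes and determinism

Default experiment sizes — 22,500 simulations per population, 5,000
profile samples per model, 100 recovery replicates, 200 × 500 calibration
— run in about a minute on one CPU; all randomness flows from a single
root seed (recorded in outputs alongside the tool version, config hash,
and input checksums), and re-running any subcommand with the same inputs
and seed reproduces identical tables.

## Known limitations

- One global α shared across individuals, loci, and strands; no
  per-individual or damage-type error rates.
- Loci are assumed independent (no linkage) and individuals unrelated;
  the audit quantifies exposure to the latter but no correction is made.
- The frequency filter and LR inherit whatever ascertainment produced the
  panel; the package does not model panel ascertainment.
- K-category generalization (α/(K−1)) covers REF/ALT-style two-category
  loci (e.g. indels detected upstream), but the bundled tooling defaults
  to the four nucleotides.
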