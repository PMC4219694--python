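# Methods

## The scientific question and the procedure

Ultra-conserved elements (UCEs) are stretches of ≥ 200 bp with (near-)
perfect identity across human, mouse and rat. Even so, human populations
carry single-nucleotide variants (SNVs) inside them. If negative selection
acted on each element as a block, variants of any population frequency
should be scattered indifferently across its positions. If instead
constraint is resolved at the single-nucleotide level, variants that have
risen to appreciable frequency should occupy the positions that tolerate
change — the relatively less conserved nucleotides — and should avoid
positions with a concrete molecular role, such as transcription-factor
binding sites (TFBS).

The pipeline operationalises that contrast in three stages:

1. **Characterization.** SNVs from one or more call sets are folded to
   minor allele frequency (MAF ∈ [0, 0.5]) and stratified: *rare*
   MAF < 0.005, *prevalent* MAF > 0.05, *intermediate* otherwise.
   Boundary values are assigned to the intermediate class — the defining
   inequalities are strict, and keeping the outer classes open makes
   rare/prevalent labels conservative. Summaries: SNVs per Mb of target per
   sample (count / (span in Mb) / samples), and cross-dataset sharing
   (Venn-cell) counts on the variant key (chrom, pos, alt).
2. **Conservation.** Per-base phyloP-like scores (positive = conserved,
   negative = accelerated) are extracted at variant positions and compared
   between classes with the two-sided two-sample Kolmogorov–Smirnov test
   (asymptotic p). The reference distribution is an equal-size random draw
   from the element universe, *composition-matched*: exact stratified
   sampling on the binary reference-base class {G,C} vs {A,T} at the query
   set's proportions, with largest-remainder apportionment of the two
   stratum counts. Its ECDF gets a pointwise 95% bootstrap envelope.
   Positional context comes from (a) the relative position of each variant
   along its host element (start = 0%, end = 100%; flanks of one element
   length map to [−100, 0) and [100, 200)), and (b) pooled score samples of
   the 3 bases immediately 5′ and 3′ of each variant (variant base
   excluded).
3. **Enrichment.** Per class, TFBS overlap is tested against an equal-size
   composition-matched null with Pearson's 2×2 chi-squared and reported as
   overlap relative to random (1.0 = no difference). Separately, 100 sets
   of 1000 positions are resampled from a position universe and per-set
   overlap counts summarised (mean, percentile 95% CI); two universes are
   compared with a two-tailed Mann–Whitney test on the count vectors. The
   package uses this to compare the conserved element universe against
   dense super-enhancer territory.

## Statistical and numerical choices

- **Coordinates** are 0-based half-open everywhere internally (BED
  convention); VCF and fixedStep wiggle are converted at ingestion. Strand
  is ignored. Book-ended intervals merge.
- **Chi-squared** is computed without continuity correction — the plain
  Pearson statistic on the 2×2 table; at the position counts in scope the
  correction is immaterial. An expected cell < 5 sets a flag on the result
  (the test is still computed); a zero margin (e.g. an empty feature track)
  yields a NaN-statistic result flagged degenerate plus a warning.
- **Mann–Whitney** uses exact enumeration when both count vectors are
  shorter than 20 and tie-free, otherwise the normal approximation with tie
  correction. Fully tied inputs give p = 1 by convention.
- **Resampled sets** are drawn without replacement within a set but
  independently across sets, keeping per-set counts i.i.d. for the rank
  test. The alternative (mutually exclusive sets) would introduce negative
  dependence and is not what a repeated-resampling design implies.
- **ECDF band**: the point ECDF is the standard right-continuous empirical
  CDF; the envelope is the pointwise 2.5/97.5 percentile of B = 1000
  bootstrap-resampled ECDFs, evaluated on the sorted unique sample values
  (exact) or a caller-supplied grid (512 points for plotting). Raw
  pointwise percentiles can fail to bracket the point ECDF at extreme grid
  points, so the envelope is clipped to contain it, preserving
  lower ≤ point ≤ upper. Pointwise (not simultaneous) coverage is the
  target; the band's job is per-position display, and its measured
  pointwise coverage at n = 500 is ≈ 95% against a known continuous truth.
- **G/C-matched sampling** never repeats a position within a draw; stratum
  counts are deterministic given the target and n, so only the positions,
  not the composition, vary between seeds. A stratum with too few positions
  raises an error naming the stratum. The binary G/C-vs-A/T correction is
  deliberate — no dinucleotide or mappability refinement is attempted.
- **Shuffle** (length-preserving random re-placement) retries a bounded
  number of times against the exclusion track and errors out rather than
  looping forever; by default intervals stay on their own chromosome, with
  an option to free the chromosome (target drawn proportionally to its
  count of valid start positions). An exclusion track (e.g. assembly gaps)
  can be supplied; none ships by default.
- **Seeding**: every stochastic routine accepts a NumPy `Generator` or a
  seed; the pipeline and generator derive per-stage named substreams from
  one top-level seed (CRC-keyed `SeedSequence`), so stages are individually
  reproducible and a re-run writes byte-identical tables.
- **Degenerate inputs**: score lookups are explicit about missing positions
  (NaN + a reported list; > 5% missing warns, all-missing errors); MAFs
  outside [0, 0.5], inverted intervals, ref-mismatched variant records and
  undersized pools all raise typed errors rather than propagating garbage.

## The synthetic scenario

The generator's defaults define the study conditions used by the tests and
the acceptance script:

| parameter | default | rationale |
|---|---|---|
| genome | 1 chromosome × 10 Mb | large enough for sparse elements, minutes-fast |
| elements | 300 × 200–600 bp, ≥ 2 kb apart | matches the ≥ 200 bp element definition; sparse like real UCEs |
| background G+C | 0.41 | human-genome-like |
| element A/T fraction | 0.62 | conserved elements are AT-rich |
| element score | Normal(3.0, 0.7) | strongly positive phyloP-like values |
| relaxed positions | 15% of element bases, Normal(0.0, 0.7) | the within-element positions under relaxed constraint |
| background score | Normal(0.0, 0.8) | neutral flanks/SE territory |
| variants | 2000 per class | rare uniform; intermediate/prevalent rejection-sampled with acceptance logistic in −β·score, β = 0.75 / 1.5 |
| MAF draws | U(0.0005, 0.005) / U(0.005, 0.05) / U(0.05, 0.5) | class-consistent by construction |
| TFBS cover | 40% of element bases (score-coupled), 2% background | element territory enriched for binding features |
| SE regions | 60 × 2–10 kb, 70% cover | a dense, non-conserved contrast universe |

Design choices worth recording:

- **Score-coupled features.** Density parameters alone cannot produce
  prevalent-variant TFBS depletion: if features were placed uniformly
  within elements, variant placement (which depends on score) would be
  independent of them. The generator therefore couples the per-base cover
  probability to the score through a logistic weight (slope 2.0, centred
  between the relaxed and conserved means), rescaled by bisection so the
  expected in-element coverage is exactly the configured density. This
  encodes the biological hypothesis itself: conserved positions are
  conserved *because* they are bound.
- **Per-base Bernoulli features.** Feature tracks are merged runs of
  independent per-base draws. Realized coverage is then exactly binomial —
  convenient for oracle checks — but the resulting intervals are much
  shorter than real clustered ChIP-seq regions. All downstream statistics
  consume only per-base overlap flags, so interval length never enters.
- **Gaussian scores.** Real phyloP values are alignment-derived and heavy
  tailed; the analyses use only ranks and ECDFs, so any continuous family
  with the configured location contrast gives the same behaviour.
- **Drawn, not evolved, MAFs.** There is no coalescent or demographic
  model; frequency classes are assigned, not emergent. The generator can
  therefore calibrate and power the *statistics*, not validate population-
  genetic inference.
- The score track covers the analysis universe only (elements ± one element
  length, plus SE regions), bounding memory by the universe rather than the
  genome.

What passing tests show — and do not show. Against this generator the
pipeline recovers, with correct direction and significance, the three
qualitative patterns it is built to detect (prevalent-vs-rare conservation
shift; prevalent TFBS depletion with rare ≈ random; dense-universe >
sparse-universe per-1000 overlap), and reports null results at the nominal
rate when the effects are switched off (β = 0, uniform features). That
demonstrates the statistical machinery is correct and calibrated. It does
not certify performance on real data, where scores are spatially
autocorrelated, base composition is structured beyond a binary G/C class,
feature intervals are long and clustered, and allele frequencies carry
demographic history.

## Problem sizes

Unit tests run on a scaled-down scenario (400 kb genome, 40 elements,
200 variants per class). Calibration suites use 1000 simulations for the
KS null-rejection rate and 200 for the chi-squared depletion report and
the ECDF band coverage; effect recovery uses 100 independently seeded runs
at the full default scenario. These sizes keep the complete suite at a few
minutes on one core while leaving Monte-Carlo error well inside the
asserted bands.

## Known limitations

- The caller-concordance step models consensus as a key intersection of two
  call sets; no variant caller is re-implemented, and the frequency of a
  consensus record follows the first (pooled-caller-analog) argument.
- VCF ingestion trusts the allele-frequency INFO field; pooled-read
  recomputation of frequencies is out of scope.
- No multiple-testing correction is applied across per-class tests by
  default, mirroring the per-set testing design; a Bonferroni option exists
  on the reporting side but is off.
- bigWig score tracks are not read natively; convert to bedGraph/wiggle
  first.
- The relative-position mapping assigns a flank variant ambiguous between
  two elements to the nearer one (ties to the upstream element) and logs
  the count; variants farther than one element length from every element
  are an error, not a silent drop.
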