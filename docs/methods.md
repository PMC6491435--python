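# Methods

This note documents the models, procedures and numerical choices behind
seqmate, what the synthetic-data generator does and does not emulate, and
the known limitations of the approach.

## Read quality control

Reads containing any `N` are discarded outright; there is no quality
trimming (FASTQ qualities are parsed and ignored) and no adapter handling.
The surviving redundant (R) list is collapsed to a non-redundant (NR)
sequence → multiplicity map; the NR:R ratio ("complexity") is a
library-diversity diagnostic in (0, 1]. Per-base composition is computed on
accepted reads, with the pre-filter matrix also retained, since either
convention is defensible. Variable-length reads are tolerated (composition
is normalized per position by coverage), although the intended input is
fixed-length 50-nt single-end reads.

## Ungapped matching

The mapping contract is: full-length, ungapped, Hamming distance ≤ 1, all
hits on both strands reported. The implementation is exact, not heuristic:
any window within distance 1 of the read must contain one of the read's two
halves verbatim (pigeonhole), so an exact-lookup table over all target
substrings of the two half-lengths cannot miss a candidate; every candidate
window is then verified by direct comparison. Because the guarantee rests
on two seeds, `max_mismatch` is restricted to {0, 1}; requesting more is an
error rather than a silent downgrade. Coordinates are 0-based half-open
internally and 1-based in exported TSV/SAM. The index is rebuilt per run —
there is no serialization and no genome-scale engineering; the intended
scale is thousands of transcripts, not mammalian genomes.

rRNA exclusion applies the same contract against the rRNA subset of the
reference and takes precedence: a read hitting both rRNA and mRNA is
excluded.

## Normalization

Depth normalization is by **subsampling without replacement** to the
minimum post-filter depth across samples (overridable), implemented as a
single multivariate hypergeometric draw over the NR view — statistically
identical to shuffling the redundant read list and truncating, without
materializing it. Abundance is the algebraic sum of the multiplicities of
distinct incident reads; a multi-mapping read contributes its full
multiplicity to every transcript it hits (fractional splitting is not
used), and multiple hits of one read within one transcript count once.

Quantile normalization forces every sample onto the per-rank mean of the
sorted columns. Ties within a sample receive the mean of the normalized
values across their tied ranks, the standard treatment; note this means
the post-transform sorted vectors of samples with ties agree only up to
tie blocks. Within-sample rank order is always preserved, as is the grand
matrix mean. Normalization state is tracked on the matrix and may only
move forward (raw → subsampled → quantile_normalized).

A practical caveat observed in end-to-end simulations: with very few
transcripts the common rank grid is coarse and genuine fold changes at the
extreme ranks are compressed. Pipelines on toy references (tens of
transcripts) should expect attenuated effect sizes; at hundreds of
transcripts and above the effect is minor.

## Differential expression

Effect size is the log₂ offset fold change OFC(a,b) = log₂((a+c)/(b+c))
with offset c = 20, which bounds the influence of low-abundance noise
(OFC → 0 as both abundances → 0) and keeps every value finite.
Transcripts below the noise floor (100) in *every* sample are removed;
dropping only all-sample-low rows deliberately keeps condition- and
tissue-restricted transcripts.

The two-group call is interval-based: each group's replicates are
summarized by their min–max envelope ("maximal intervals"), and a
transcript is DE iff the envelopes are disjoint **and** the OFC between
the two nearest bounds exceeds 1 in magnitude. This conservative-bound
rule is stricter than comparing means — a single discordant replicate
vetoes the call — which is the point: with three replicates and no
distributional model it controls false positives tightly (measured null
FPR ≪ 1% at negative-binomial dispersion 0.1). The cost is sensitivity:
at dispersion 0.1 the rule detects ~66% of genuine 4-fold changes, rising
to ~88% at dispersion 0.05. Both numbers are measured by the test suite
and the acceptance script; users should treat the caller as
high-precision, moderate-recall. The mean-based OFC is reported alongside
as a point estimate. No multiple-testing correction exists because no
p-values exist.

The hierarchical variant filters and calls within each tissue separately
and labels transcripts `shared` (above floor in every tissue) or
`tissue_specific`. Reference-gene screening selects transcripts above
500,000 in every sample whose mean-based |OFC| is ≤ 0.0001 both between
regimes within each tissue and between tissues; a permutation-based
stability test is not implemented.

## Mating isolation statistics

Pair counts are stored female-row × male-column with explicit type labels;
two-letter pair codes are never parsed, avoiding a common source of
transposition errors. From counts n, availabilities f, m and total T:
e_ij = T(f_i/Σf)(m_j/Σm), s_ij = rowsum_i·colsum_j/T, PTI = n/e,
PSI = n/s, PSS = s/e. Cells with zero denominators are NaN (undefined),
never zero. For two types, I_PSI = (ΣPSI_homo − ΣPSI_hetero)/ΣPSI ∈ [−1,1];
IA_PSI is the ratio of the two heterotypic PSI cells in a configurable
order (default: second/first with first = (type₁ female, type₂ male)),
chosen so 1 means no asymmetry and the direction of deviation identifies
the favoured pair class; W_i is the mated fraction of type i normalized by
the fittest type, so max W = 1.

**Bootstrap.** The T observed pairs are resampled multinomially from the
observed pair frequencies (availability margins fixed; pairs treated as
independent, appropriate when only a fraction of possible matings is
sampled). The two-tail p is the doubled smaller tail around the null
(0 for I_PSI, 1 otherwise), with resamples exactly at the null counted in
both tails — a conservative convention for discrete statistics. Resamples
on which the statistic is undefined are discarded and counted; more than
50% undefined aborts with an explicit error. Resampling is vectorized
(all B resamples evaluated as a stacked B×K×K array), so 10,000 iterations
cost milliseconds. Under the sequential null generator the I_PSI test's
measured type-I error at nominal 0.05 is 0.049 ± 0.005.

**Combination.** Replicate trials are pooled by elementwise summation
before analysis; independent comparisons combine via Fisher's sum of logs
(−2Σln p ~ χ²_2k). Bootstrap p-values of exactly 0 are clamped to
1/(2·n_boot) — the resolution of the bootstrap — with a warning.

## Synthetic-data generator

The generator is first-class, tested code and defines the conditions under
which the pipeline is validated.

- **Transcriptome**: uniform-random sequences (default 200–400 nt), a
  configurable fraction flagged rRNA. Real transcriptomes have composition
  bias, repeats and shared k-mers between paralogs; random sequences make
  cross-mapping rare, so multi-mapping behaviour is exercised by dedicated
  unit fixtures rather than by the generator.
- **Reads**: 50-nt single-end, source transcript ∝ abundance × effective
  length (length − 49), start position uniform; per-base substitutions to a
  different base, then per-base N replacement (an N never counts as a
  substitution in the truth table). No indels, no paired ends, no quality
  simulation (constant placeholder quality), matching the matcher's
  contract rather than a sequencer error model.
- **Counts**: negative binomial with variance = mean + φ·mean² (φ → 0 is
  Poisson; φ = 0 draws Poisson directly). Base means are log-normal
  (σ = 1); a chosen fraction of genes receives a ±lfc log₂ shift split
  symmetrically between the two regimes, then per-regime relative
  abundances are scaled to a common library size. The returned matrix is
  marked depth-matched (state `subsampled`), since all samples share one
  nominal depth by construction. Real RNA-seq additionally has gene-length
  effects, GC bias and correlated genes; none are modelled, so passing
  recovery tests demonstrates correctness of the calling rule, not
  real-data performance.
- **Mating trials**: sequential sampling without replacement — at each
  step pair (i,j) forms with probability ∝ remaining_f_i × remaining_m_j ×
  α_ij, both individuals removed — with the default design 25+25 per sex
  per type and a 25-pair stopping rule (half the population, so diminishing
  choice stays modest). α all-ones is random mating; the 30-minute clock of
  a physical assay has no analogue (no time dimension). Recovery checks:
  mean I_PSI is 0 under α = 1 and increases monotonically in the
  homotypic/heterotypic propensity ratio (≈ 0, 0.35, 0.62, 0.79 at ratios
  1, 2, 4, 8).

## Problem sizes used in validation

Matcher exactness is checked against a dense all-offset Hamming scan on
200 random instances (2–5 targets of 40–300 nt, reads 20–50 nt, 10 reads
each, both strands). DE operating characteristics use 2,000 genes × 3 vs 3
replicates × 20 seeds at library size 2 × 10⁶. Bootstrap calibration uses
2,000 simulated null trials with 2,000 resamples each; the exact-enumeration
cross-check runs at T = 3 where full enumeration is feasible. The
end-to-end expression fixture is 100 transcripts × 10,000 reads × 12
samples. These sizes make the full validation run in well under a minute
per component while keeping Monte-Carlo error far below the asserted
margins.

## Known limitations

- The matcher is exact but not engineered for genome-scale references or
  10⁷-read libraries; the intended use is transcript-scale references.
- The DE caller has no inferential model: no p-values, no shrinkage, no
  replicate weighting. Its sensitivity depends steeply on biological
  dispersion (see above).
- I_PSI and IA_PSI are restricted to two types; the per-cell coefficients
  support K > 2.
- The bootstrap conditions on the observed total T and pair frequencies
  only; uncertainty in the premating pools is not propagated.
- Quantile normalization assumes samples share a common underlying
  distribution; designs where most of the transcriptome genuinely shifts
  violate this and will see effect-size compression.
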