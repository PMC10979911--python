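# Methods

`sevqc` detects and quantifies residual Sendai-virus reprogramming-vector
expression in RNA-seq data. This note describes the statistical model, the
synthetic data the package validates itself against, and the numerical
choices that were genuinely open.

## The exogeny statistic

Reprogramming with Sendai-based vectors (e.g. CytoTune 2.0) delivers the
Yamanaka factors (OCT4/POU5F1, SOX2, KLF4, MYC) as bare coding sequences on
a cytoplasmically replicating RNA genome. Endogenous factor mRNAs are
transcribed and spliced as CDS+UTR units; vector-derived transcripts carry
the CDS only. Read density over the two feature classes therefore
separates the sources. For one factor transcript in one sample:

    cds_density = (cds_count / s_j) / L_cds
    utr_density = ((utr5_count + utr3_count) / s_j) / (L_utr5 + L_utr3)
    ratio       = cds_density / utr_density

where `s_j` is the sample's median-of-ratios size factor (it cancels in the
ratio and is retained only so densities are reportable on a common scale).
The 5' and 3' UTRs are pooled into a single UTR feature before division;
per-end densities are available in the feature-count table as diagnostics.

Under uniform fragment sampling, if a factor is present at `n` endogenous
and `e` exogenous (CDS-only) copies, per-base CDS coverage is proportional
to `n + e` while UTR coverage is proportional to `n`, so

    E[ratio] ≈ 1 + e/n        (`expected_mixture_ratio`)

The ratio is ~1 for purely endogenous expression and grows linearly with
the exogenous load: a ratio of ~100 corresponds to e/n ≈ 99, the scale
observed for MYC under persistent vector expression in naive culture
media; ratios above 10 correspond to e/n ≈ 9 (SOX2/KLF4 scale).

Conventions: no pseudocount is applied; zero UTR counts with positive CDS
counts yield `+inf` with an explicit `utr_zero` flag. Records with fewer
than 30 raw CDS+UTR counts are flagged `low_expression` (configurable).
Transcripts modeled without UTRs (the viral genes) have no defined ratio
and raise instead of returning a number.

### Finite-read-length bias

The `1 + e/n` oracle is the short-read limit. With reads of length `L`
counted by their 5' start and credited to every feature they overlap by
≥1 base, the expectation for a single-sample mixture is

    E[ratio] ≈ 1 + (L-1)/L_cds + (e/n) · (1 - (L-1)/L_tx)

because junction-spanning reads inflate the CDS count of endogenous copies
while exogenous (CDS-only) fragments can never straddle a junction. At the
package's default 50 bp single-end reads this bias is ~2% for the MYC
geometry and smaller elsewhere; at 100 bp it would reach ~4%. The 50 bp
default was chosen to keep the generator's output faithful to the oracle
the statistic is validated against, and matches the short single-end
libraries common in the bulk RNA-seq studies this analysis targets.

## Viral expression summary and persistence call

Viral genes are modeled as UTR-less single-exon transcripts on the
vector's genome (Sendai gene order N-P-M-F-HN-L). The commercial kit's F
gene deletion is represented by a `deleted_genes` set: the F interval is
retained for coverage reporting, but F never contributes simulated reads
and never enters the mean viral TPM (`viral_summary`). A sample is called
vector-positive when mean viral TPM ≥ 0.1 **and** total viral raw reads
≥ 10; both thresholds are deliberately conservative, configurable, and
should be tightened only with knowledge of the library depth.

## Serial-passage selection model

Cultures are modeled as a two-type population: vector-positive cells with
per-passage growth advantage `w`, negative cells with advantage 1. The
positive fraction `p_t` then follows an odds multiplication,

    odds_{t+1} = w · odds_t,     odds = p / (1 - p)

Bulk viral expression at passage `t` is `p_t · v` of the library, where
`v` (`per_cell_viral_expression`, default 0.05, i.e. viral RNA is 5% of a
positive cell's transcriptome) sets the saturation scale; observed counts
are Poisson at the configured sampling depth (default 10^6).

`estimate_enrichment` fits log2(expression) against passage number by
ordinary least squares and reports `2^slope` as the per-passage rate. Two
caveats follow directly from the model:

* **Saturation.** Once positives dominate (`p_t` → 1) expression
  plateaus, so the log-expression slope underestimates `w`. Starting from
  p0 = 10^-3 with w = 2 over 10 passages the plain fit returns ~1.85-1.9;
  with w = 3 it cannot recover the rate at all. When the saturation scale
  `v` is known (it is, for simulated data; for real data it would require
  an estimate of per-cell viral load), passing `expression_scale = v·10^6`
  converts expression to implied positive fractions and fits log2 *odds*,
  which is exactly linear under the model and recovers `w` within a few
  percent at these depths.
* **Cumulative enrichment.** The quantity a constant per-passage
  advantage compounds into is the odds ratio between first and last
  passage (`cumulative_cell_enrichment` = w^n exactly), not the expression
  fold, which saturates below it. A ~1,000-fold difference accrued over 10
  passages corresponds to 1000^(1/10) = 1.995 ≈ 2-fold per passage
  (`per_passage_fold`). The expression fold is reported separately
  (`cumulative_expression_fold`) and is the right quantity when positives
  remain rare throughout.

Zero-expression points are excluded from the fit with a warning; fewer
than two usable points is an error.

## Quantification

Reads are assigned by exact k-mer voting against the spliced transcript
sequences of the combined host+viral reference (k = 31, both strands
indexed; the reverse complement of every reference k-mer maps to the same
hits). Each read k-mer votes for the transcripts containing it; maximal-
vote transcripts win, ties split the read into equal fractional weights
(no EM — the ratio statistic needs positional density, not isoform
resolution). A read needs at least `max(1, n_kmers - 3k)` votes, which at
50 bp/k=31 reduces to a single exact k-mer; note that with these
parameters a substitution in the central 12 bases of a read destroys all
of its k-mers, so ~1% of reads are unassigned at the generator's default
0.001 substitution rate. This loss is position-uniform and cancels in the
ratio.

Feature counting credits a read's weight to every feature (CDS, UTR5,
UTR3) it overlaps by at least one base. Coverage tracks bin reads by
their 5'-most base into 100 bp bins, so bin sums equal assigned read
totals exactly. Counting is unstranded.

## Normalizations

* **Size factors**: median-of-ratios. Features with any zero count are
  excluded (the geometric mean is computed in log space); the median is
  taken over log-ratios, so an even number of qualifying features yields
  the geometric midpoint of the two central ratios — this matches the
  standard estimator bit-for-bit (verified against Bioconductor's
  implementation during development). Raw factors are reported without
  renormalization; consequently scaling one library by λ scales its
  factor by λ^((m-1)/m) and factor *ratios* by λ exactly.
* **TPM**: counts / length, rescaled to 10^6 per sample; all-zero samples
  stay zero. Gene length is the MANE-select transcript's spliced length
  when flagged, otherwise the longest transcript.
* **CPM tracks**: bin value / size factor / mean per-sample assigned read
  count × 10^6. The "mean read count" is taken over the sample set passed
  to the run — whether that set is a whole study or one figure panel is a
  caller decision.
* **Min-max rescaling**: (x - min)/(max - min); constant tracks map to
  zeros rather than NaN.

## Synthetic data: what it emulates, what it does not

The generator builds four factor loci whose CDS/UTR lengths, exon counts
and strands approximate the real MANE transcripts (SOX2 single-exon,
POU5F1 and KLF4 on the minus strand), each on its own contig with random
uniform base composition, plus a 15.4 kb Sendai-like genome with the six
canonical genes and F marked deleted. Reads are single-end, fixed-length,
uniform-start, with substitution errors only.

It deliberately does **not** model: fragment-length distributions,
positional/GC/sequence bias, paired ends, indels, quality-score
structure, isoform diversity beyond one transcript per factor, homology
between factor paralogs, or 3'-biased library chemistry. Passing tests
therefore show the estimators are correct *under the stated sampling
model*; on real data the endogenous baseline ratio can deviate from 1
(e.g. 3' coverage bias inflating UTR3 density), which is why practice on
real data should benchmark ratios against transgene-free control samples
rather than against the analytic baseline.

Problem sizes used in the validation suite: 2×10^5 reads per simulated
sample for ratio recovery (giving Monte-Carlo SEs of ~2.5% on the mixture
ratios), 10^6-read Poisson depth over 11 passage points for enrichment
recovery, and 100 random 50×6 matrices for the size-factor oracle.

## Known limitations

* The k-mer voting assigner is exact-match only; at high error rates or
  k close to the read length its sensitivity drops sharply (see above).
  It is a desk-scale stand-in with the same counting semantics as an
  aligner-based workflow; external aligner output can be ingested via the
  feature-count TSV bridge (`sevqc ratio`).
* `estimate_enrichment` assumes a constant `w` across passages; changing
  media or bottlenecks between passages violate this.
* The persistence call is a threshold rule, not a hypothesis test; at
  very low depth "negative" means "below detection", not "vector-free".
* Viral genes are quantified against the wild-type gene set; vectors with
  rearranged genomes (e.g. factor insertions altering gene boundaries)
  need a custom gene table.
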