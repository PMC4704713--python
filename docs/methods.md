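# Methods

`maspect` analyzes mutation-accumulation (MA) experiments of the classic
microbial design: many initially identical haploid lines are propagated
through repeated single-colony bottlenecks, so that spontaneous mutations
fix essentially at random, and are then whole-genome sequenced against their
common ancestor.  The package consumes post-variant-calling artifacts (a
reference FASTA, per-line and ancestor VCFs, exclusion BED, feature
annotation, replication-origin and transcript-abundance tables) and produces
mutation-rate, spectrum, context, covariate, and error-rate estimates.  Its
defaults mirror a fission-yeast experiment of 79 lines passaged for ~1952
cell generations over a 12.47-Mb reference.

## Mutation classification

Calls pass a support filter (>= 4 reads, >= 75% backing the alternate
allele; both thresholds inclusive) and ancestor subtraction (a call
identical in chromosome, position, ref and alt to an ancestor call is an
ancestral marker, not a new mutation).  Same-length multi-base
substitutions are decomposed into per-base substitutions first.  Variants
are then clustered by single linkage on start positions with a 50-nt gap:
the resulting clusters are exactly the connected components of the
"within 50 nt" proximity graph, which the test suite verifies against a
brute-force union-find oracle.

* 1 member: SNM, insertion, or deletion by allele lengths
  (indel size = |len(alt) - len(ref)|, small means < 50 bp);
* 2 SNMs: one double-SNM event;
* \>= 3 members: one complex event;
* deletions of 50-1000 bp: medium deletions, always their own event
  (they are pulled out before clustering);
* a 2-cluster containing an indel has no defined class; its members are
  classified independently and the occurrence is logged.

Cross-contamination screening drops one member of any line pair sharing an
identical new mutation, chosen by a seeded uniform draw (default seed 2015)
so reruns are reproducible.

## Rates and spectrum

A class rate is `count / (n_lines x G x L)` per base per generation.  `L`
defaults to the full reference length rather than the exclusion-masked
length; this is the only convention that reproduces all of the published
per-class rates from their printed counts simultaneously, and a masked-
length mode is available (`analysis.rate_denominator: masked`).  The
standard error is the standard deviation of per-line rates divided by
sqrt(n_lines) — each line is an independent replicate of the mutational
process, so across-line spread is the natural uncertainty.

The six strand-collapsed substitution classes are normalized by the genomic
abundance of the source base pair (conditional per-site rates).  Derived
summaries: Ts/Tv (count ratio), within-transition and within-transversion
fold biases, the overall G/C->A/T fold, and the mutational-equilibrium G/C
content u/(u+v), where u is the conditional A/T->G/C rate and v the
conditional G/C->A/T rate (composition-preserving changes do not enter).
Equilibrium is invariant to rescaling all rates.

Population-genetic derivations use the haploid coalescent expectation
pi = 2 Ne mu, and strain divergence in generations is n_diffs / (mu L).

## Per-line count distribution

Per-line SNM counts are fit by maximum likelihood under Poisson and
negative binomial (Gamma-Poisson) models; the NB is parameterized by mean m
and overdispersion k with variance m + m^2/k, the mean MLE is the sample
mean, and k is profiled numerically on log scale.  Goodness of fit is a
chi-square over count bins pooled (from the upper tail) until every
expected count is >= 1, with df = bins - 1 - n_params.  Model comparison
uses AIC and the relative likelihood exp((AIC_min - AIC)/2).  ML estimates
of k carry a known upward bias at n ~ 80 lines; the tests check consistency
at large n and distributional recovery at experiment scale.  When all lines
carry identical counts the NB is degenerate (k -> infinity) and only the
Poisson fit is reported.

## Trinucleotide context

Each analyzable position (unambiguous, unmasked, with two valid neighbors)
belongs to one of 32 strand-collapsed trinucleotide classes; the collapse
representative is the lexicographic minimum of the trinucleotide and its
reverse complement, displayed in the field's aCa style.  A class's relative
rate is its per-site SNM rate over the genome-wide per-site rate computed
from context-assignable counts and sites, so the site-weighted mean over
classes is exactly 1.

Class-level testing compares per-line relative rates against 1 with a
one-sample t-test, separately for the 16 A:T-center and 16 G:C-center
classes, each normalized by its own base set's pooled rate (G:C pairs are
globally hotter, and pooling them with A:T would flag every G:C class).
Significance uses the Bonferroni threshold 0.05/16 = 0.003125.  The test
is **one-sided for elevation**.  This is a deliberate design choice: per-line
class counts are sparse (mostly 0 or 1), and while the t approximation is
adequate in the elevation direction, it is severely anti-conservative for
deficits — a class with a handful of expected events and none observed
produces a tiny artificial variance and a huge negative t.  In null
simulations a two-sided flag produced family-wise false-positive rates near
50%, essentially all from deficit artifacts; the one-sided elevation test
is calibrated (family-wise rate well under 5% over hundreds of null
replicates) and matches the scientific question (hypermutable contexts).

CpG analysis is strand-collapsed (center C with 3' G, or center G with 5'
C).  Directional counts at CpG sites are compared with the genome-wide
C:G-source spectrum by a 2-df chi-square, falling back to an exact
multinomial test when any expected cell is below 1; the same machinery
serves single-class direction tests (exact below n = 5).

## Covariate binning

Three covariates partition the genome: G/C content of non-overlapping
10-kb windows (1% bins, floored; trailing short windows are flagged and
excluded), replication time (each position inherits the firing minute of
the nearest same-chromosome origin, ties toward the earlier-firing origin,
1-minute bins), and expression (per-transcript median log10 FPKM across
replicates; a zero bin plus fourteen 0.25-wide bins up to 3.5, values above
3.5 clamped into the top bin, positions outside transcripts in bin 0).

A bin's relative rate is its per-bp SNM rate over the genome-wide rate.
Bins are merged, in covariate order, into groups holding roughly equal SNM
counts: accumulate bins until a group reaches total/n_groups SNMs, then
start the next; the last group absorbs the remainder.  Group summaries are
bp-weighted means, so the bp-weighted mean over groups is exactly 1.  The
group SE is sqrt(weighted between-bin variance / n_eff) with
n_eff = (sum w)^2 / sum w^2; group differences use a two-sample z on the
weighted means.  Null simulations show per-covariate false-positive rates
consistent with the nominal 5%.

## Enrichment, consequences, error rates

Feature enrichment uses Fisher's exact test on the 2x2 table of events
in/out of a feature against genome bp in/out (bp as trials); expected
counts are n_events x genome fraction and sum to n_events.  Chromosome
homogeneity is a chi-square against length-proportional expectations.

Coding consequences come from gene models (CDS exon blocks with strand);
a substitution is classified synonymous / missense / nonsense /
stop-retained (plus stop-lost, splice within 2 nt of an intron boundary,
intronic) via the standard codon table, and coding indels are frameshift or
in-frame by length change mod 3.  The expected synonymous:missense ratio
under the observed spectrum is computed by Monte Carlo over random coding
sequences drawn from a codon frequency source, with substitution sites and
directions weighted by the conditional spectrum; an exact enumeration over
all single-base codon changes serves as the oracle and the large-n limit.
The codon source defaults to the supplied annotation's usage; this choice
shifts the expected ratio and is surfaced as a parameter.  The z-test
against an observed ratio is a one-sample two-proportion z on the
synonymous fraction with the observed syn+mis count as n; the published
analysis did not state its construction, so printed z-values are matched
only approximately.

False negatives are estimated from ancestral markers: every marker should
be re-detected in every line, so the per-class rate is
misses / (markers_of_class x lines).  The probability that a marker site
mutates again during the experiment (which would masquerade as a miss) is
the linear approximation markers x lines x G x mu, with a warning when it
exceeds 0.1.

Experiment-scale statistics: generations per transfer g = log2(mean cells
per colony) (2^g cells after g doublings with no mortality), total
generations = mean g x transfers.  The within-line effective size of a
colony grown from one cell is the harmonic mean of census sizes
2^0 ... 2^(g-1): Ne = g / sum 2^-i; its reciprocal is the drift barrier,
the selection-coefficient magnitude below which selection cannot beat
drift.  At g = 19.52 this formula gives Ne ~ 9.8 cells, whereas the
modeled experiment reported 10.26 from its unpublished cell-count series;
downstream thresholds therefore accept the reported Ne as data.

## Synthetic data generator

The generator emulates everything downstream of variant calling with known
truth.  Genome: chromosomes (default three, fission-yeast-like length
proportions) drawn from a first-order Markov chain whose default transition
matrix has identical rows — i.e., i.i.d. bases at the target G/C fraction
(0.3606), which vectorizes; exclusion blocks mimic telomere ends and a
centromeric middle (~3.8% total); genes with occasional introns are placed
to hit 57% coding / 3% intron; origins are placed uniformly with firing
minutes on 68-85; transcript expression mixes silent genes with truncated
normal log10 FPKM on (0, 3.5].

Lines: each line's SNM total is drawn NB(mean = mu G L_d, k = 2.06)
(Poisson when k is None), classes multinomial from the six-class
proportions, and positions sampled from source-base site pools with
per-class context-multiplier weights.  The default six-class proportions
are derived from the modeled experiment's printed biases (Ts/Tv 0.72,
within-transition fold 2.02, within-transversion fold 4.55, overall
G/C->A/T fold 2.97 at G/C 0.3606); the G:C<->C:G vs A:T<->T:A split is not
printed and is fixed by equating those conditional rates.  Indels are
Poisson with a 6.13-fold insertion bias and geometric sizes (means 1.6 and
3.1 bp); doubles are two SNMs within 50 nt; complex events are 3-5
variants within 50 nt with an indel in half of draws.  Ancestral markers
(80 SNM / 120 insertion / 42 deletion) are written into every line and
then thinned by per-class dropout (defaults 1e-4 / 0.011 / 0.017) to model
detection failure; low-quality spike-in records (3 per line) exercise the
support filters.  Mutations are placed in one generative pass —
per-generation linearity makes forward simulation unnecessary for
effectively single lineages — and independent events landing within the
clustering distance are recorded as collisions so recovery tests can
account for the (rare) resulting misclassification.

`rate_denominator_bp` decouples the count expectation from the synthetic
genome's length: a 1-Mb genome with the denominator set to 12.47e6 carries
study-scale event counts (~4.1 SNMs per line) while positions and contexts
come from the smaller sequence.  Recovery is then assessed against the
effective per-base rate mu x L_d / L_genome.  What the simulator does not
model: read-level errors and coverage variation (no FASTQ), mapping
artifacts, selection during passaging, structural variation beyond
pre-called medium deletions, and genuine sequence repeat structure
(microsatellite slippage is represented only through the configured indel
rates).  Passing recovery tests therefore validates the estimators on
clean calls, not the upstream calling pipeline.

## Problem sizes and numerical choices

The test suite runs synthetic genomes of 50 kb to 1 Mb with study-scale
count expectations; recovery uses 100 seeds (rate within 2 reported SE,
six-class spectrum within simultaneous Clopper-Pearson intervals), planted
CCG x4 detection uses 25 seeds, and null calibration uses 200 replicates,
keeping the default run around a minute of CPU.  All randomness flows
through `numpy.random.default_rng` seeds; identical seeds give
byte-identical FASTA/VCF output.  Coordinates are 1-based inclusive
internally (VCF convention); BED input is 0-based half-open.  Ambiguous
bases are excluded from every denominator, and census positions whose
trinucleotide window touches a masked or ambiguous base are dropped.

## Known limitations

* The NB overdispersion k is reported as-fit (ML); no bias correction.
* Fisher tests treat genome bp as independent trials, as in the modeled
  analysis; spatial autocorrelation of features is ignored.
* Deficit-direction context effects are deliberately not flagged (see
  above); a calibrated deficit test would need an exact or resampling
  construction.
* The expected syn:mis ratio depends on the codon source distribution;
  published values are matched in design, not digit-for-digit.
* Gene models assume non-overlapping genes; an SNM in overlapping models
  would be classified against the first match.
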