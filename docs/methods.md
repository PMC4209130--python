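# Methods

## The intron-delay problem

In the early *Drosophila melanogaster* embryo the zygotic nucleus divides 13
times inside a syncytium, with the first nine cycles taking roughly 9 minutes
each, cycles 10–13 lengthening to about 17 minutes, and a roughly 60-minute
interphase in the 14th cycle during which cellularization occurs. When the
chromosomes condense at mitosis, engaged RNA polymerases are stripped off and
the incomplete nascent transcripts are degraded. A gene can therefore only
produce full-length mRNA if its primary transcript — introns included — can be
transcribed within a single interphase. At an elongation rate *v* (bp/min) and
interphase duration *T* (min), the maximum completable primary-transcript
length is *v·T*: long zygotic genes are silenced or rate-capped until the
cell cycle slows ("intron delay"). Maternally deposited mRNA is already mature
and is untouched by this mechanism, which gives the analyses below their
controls.

## Simulator

`synthetic_data.simulate_timecourse` implements the mechanism directly.

* **Schedule.** `CellCycleSchedule.drosophila_default()` uses cycle totals of
  9 min (cycles 1–9), 10/12/14/17 min (cycles 10–13), and 65 min (cycle 14,
  60-min interphase). Published observations constrain the totals but not the
  interphase/mitosis split, so the package adopts an embryology-consistent
  split: interphases of 6 min in cycles 1–9, lengthening 6.5→13 min over
  cycles 10–13, with mitoses of 3–5 min. Zygotic initiation begins at cycle 8
  (`zga_cycle`), matching the earliest detection of zygotic transcripts.
* **Kinetics.** During each interphase, eligible genes initiate as a Poisson
  process (`initiation_rate`, default 2/gene/min — the scale of an active
  early-embryo promoter firing every ~20–30 s; a literature-scale placeholder,
  configurable). Polymerases advance deterministically at `elongation_rate`
  (default 1,400 bp/min). A polymerase that reaches the transcript end
  converts the transcript to mature mRNA; splicing is treated as instantaneous
  and mature mRNA is the concatenated exonic sequence. At each mitosis entry
  every nascent transcript is destroyed with probability
  `abort_prob_at_mitosis` (default 1.0, i.e. complete abortion, modelled as
  instantaneous degradation). Mature mRNAs decay exponentially
  (`zygotic_decay_rate` 0.01/min ≈ 70-min half-life; `maternal_decay_rate`
  0.005/min, so most maternal signal is gone by gastrulation). Maternal genes
  receive a Poisson(`maternal_abundance`=50) pool of mature mRNA at t=0 and do
  not re-initiate unless `maternal_zygotic_onset` is set.
* **Sampling design.** Default `sample_times` place three collections in the
  interphases of cycles 11–13 and three during the extended 14th interphase,
  mirroring syncytial-stage timecourse designs (which devote several
  collections to cycle 14 — that is where long-gene activation unfolds).
  `independent_timepoints=True` simulates a fresh embryo pool per sample time,
  as in real collections where each window uses different embryos. This
  matters statistically: a single embryo followed through time has
  autocorrelated sampling noise (counts are cumulative), which makes
  trajectory-difference slope tests anti-conservative; independent pools make
  per-timepoint noise independent and the tests calibrated.
* **Exact law.** With abort probability 1 the simulator obeys, exactly: a
  gene completes a transcript by time *t* iff its primary length is at most
  `elongation_rate × longest_interphase_before(t)` (elapsed portion of an
  ongoing interphase included), and per-gene counters satisfy
  initiated = completed + aborted + currently nascent.

## Read sampler

`sample_reads` draws error-free 50-bp single-end reads as strand-aware genomic
intervals (6-column BED); there are no sequences, base errors, or mapping
ambiguity. Poly-A mode samples only mature mRNA; total-RNA mode adds, for each
nascent transcript, the exonic projection of its transcribed prefix. Reads are
allocated by a multinomial over the available sequence mass (valid start
positions) and placed uniformly within single exon segments; junction-spanning
reads are omitted (a ~1% fraction at 50 bp that the interval analyses could
not represent). For a pool of nascent transcripts with uniform polymerase
positions on (0, L), the read-start density is proportional to 1 − (x+r)/L,
i.e. the triangle profile up to the read-length offset r — the signature the
coverage analysis detects.

## Genome generator

`make_genome` draws primary-transcript lengths from a log-normal (median
2.5 kb, σ(log) = 1, clipped to [0.3, 150] kb — about 24% of genes at ≥ 5 kb),
optionally with different medians per origin class. Intron count per gene is
Poisson(0.5 + L/2500), leaving roughly a fifth of genes intronless, with
heavy-tailed intron lengths floored at the 42-bp minimum; exon/intron
partitions are exact (lengths sum to L). Genes are placed non-overlapping on
one chromosome with random strands. `make_planted_delay_matrix` is the
statistical (non-mechanistic) counterpart: an expression matrix in which genes
above a length threshold carry an early deficit that relaxes linearly to zero,
used when an exactly uniform "delay" effect with known truth is needed (e.g.
threshold-selection experiments).

## Quantification

Counting follows the gene-level union rule: a read counts for a gene iff the
set of genes whose exons overlap any of its bases is exactly that one gene;
otherwise it is ambiguous (≥2) or no_feature (0), and
assigned + ambiguous + no_feature always equals the input read count.
Counting is unstranded by default (a `stranded` flag restricts overlap to
same-strand features). RPKM = count / (library/10⁶ × exonic_kb), with the
library size defined as total input reads and the denominator the union
exonic length per gene. Genes are retained if RPKM > 5 at one or more
timepoints (strict inequality; an alternative threshold of 2 reproduces the
conventional robustness check). No mean–variance or GC normalization (e.g.
conditional quantile normalization) is applied: the analyses rest on
within-class temporal contrasts, for which plain RPKM suffices, and this is a
deliberate simplification. The coverage analysis additionally requires ≥ 100
mapped reads at some individual timepoint.

## Delay analysis

Genes are split at 5 kb into short (<5 kb) and long (≥5 kb) classes, on
primary-transcript length or, for cross-species work, total orthologous
intron length. `select_length_threshold` re-derives the boundary empirically:
genes are binned in 5-kb increments and per-timepoint expression distributions
are compared between all bin pairs (permuted Kruskal–Wallis, Bonferroni over
pairs × timepoints); the chosen threshold is the smallest edge above which
bins are mutually indistinguishable while each differs from every bin below.

Expression is analyzed as log2(RPKM + 1) (a `log_transform=False` escape hatch
preserves raw or already-log units). Per (origin × length class × timepoint),
the median across genes is reported with a 95% normal-approximation bootstrap
CI (10,000 resamples by default), and each class's medians are regressed on
timepoint index (OLS slope, R², two-sided slope test).

`ancova_interaction` tests whether the long/short gap changes over
development. The model is median ~ C(time) + class + time:class — the shared
time course enters as a factor and only the interaction is linear in time;
this reduces exactly to regressing the per-timepoint class difference on
timepoint index (df = T − 2). The design was chosen over the textbook
median ~ time + class + time:class because with a linear time main effect any
nonlinearity of the shared activation trajectory lands in the residual and
the interaction test loses calibration (arbitrarily conservative or
anti-conservative depending on the noise regime), whereas the factor form
cancels the shared trajectory identically; simulation places its type-I error
at 0.05 within Monte-Carlo error. A leave-one-timepoint-out loop reports
robustness of the interaction to any single timepoint.

Categorical enrichments (intronless × origin; stability × length class) use
the 2×2 Pearson chi-square with 1 df, no continuity correction by default
(Yates optional).

## Coverage analysis

For each gene, ten non-overlapping 500-bp windows are laid along the first
5 kb of the primary transcript in transcription direction (minus-strand genes
reflected). Each read is counted into the window containing its 5′-most
transcript position; window values are reads per exonic bp (windows are
genomic, intersected with exons), windows with no exonic sequence or beyond
the gene end are ignored, and each gene's windows are scaled to its maximal
window. Read-start counting (rather than per-base depth) keeps flat profiles
unbiased: per-base depth has a deterministic 5′ dip of about half a read
length that systematically tilts slopes by ≈ +0.003 per window. Per class,
per-window medians across genes are regressed on window number (1–10) to give
the coverage-decay slope; a gene-resampling bootstrap provides a slope CI,
and the per-timepoint (maternal − zygotic) slope difference is regressed on
timepoint index to test whether the nascent-transcription signature fades as
cycles lengthen. The complementary 5′:3′ statistic is the per-gene ratio of
RPKM over the 5′-most versus 3′-most 1 kb of exonic sequence (genes with
≥ 2 kb exonic only); with no pseudocount, gene/timepoints with an empty 3′
segment are excluded (a `pseudocount` flag retains them).

## Conservation analysis

Orthologous intron lengths evolve on a star phylogeny
(melanogaster/ananassae/pseudoobscura/virilis by default, the reference on a
zero-length branch and divergence increasing down the list): each intron's
log-length takes an independent Gaussian step with SD σ × branch length, σ
chosen per gene by constraint class, floored at 42 bp. Per gene the corrected
coefficient of variation CV* = (1 + 1/(4n)) × sd/mean is computed across the
n species from total orthologous intron length, with the sample (n−1)
standard deviation — the small-sample correction conventionally pairs with
it; a `ddof=0` flag gives the population form. Single-exon genes are
excluded. Expression tiers (high/low = top/bottom quartile at the first
timepoint) are computed within each origin class by default
(`within_origin=False` switches to global quartiles). Categories are compared
pairwise on mean intron length or CV* by permuted Kruskal–Wallis (10,000
permutations, add-one p-value estimator, Bonferroni over pairs). Because CV*
is biased low when mean intron length is under ~150 bp,
`sensitivity_filter_150` repeats the comparison after dropping such genes and
reports removals per category.

## Statistical machinery

* Bootstrap CIs: normal approximation, estimate ± 1.96 × sd of 10,000
  resampled statistics (the method names the approximation, so the 1.96
  quantile is the natural reading).
* Permuted Kruskal–Wallis: mid-rank H with tie correction, label-permutation
  null, p = (1 + #{H_perm ≥ H_obs}) / (n_perm + 1) — never exactly zero.
* All randomized procedures take explicit seeds and are bit-reproducible.

## Problem sizes and what the tests show

The test suite and the acceptance script run the pipeline at deliberately
modest scale — hundreds to a thousand genes, 10⁵–10⁶ reads, 100–500 replicate
simulations — chosen so the full battery completes in minutes while keeping
Monte-Carlo error well inside the asserted bands. The synthetic data carry the
statistical structure the analyses assume (timed abortive transcription,
nascent 5′ bias, independent embryo pools per timepoint, neutral-vs-constrained
intron evolution) but not many features of real embryo data: no mapping error
or multi-mapping, no 3′ bias of poly-A libraries, no isoform structure, no
spatial patterning or mitotic domains, no co-transcriptional splicing
kinetics, and transcription is homogeneous across nuclei. Passing tests
therefore demonstrate that the analysis stages correctly detect the mechanism
when it is present and stay calibrated when it is absent — not that every
real-data confounder is handled.

## Known limitations

* The union counter iterates reads in Python over an interval tree; it is
  comfortable at the 10⁶-read scale of the synthetic experiments but is not a
  replacement for compiled counters on full sequencing runs.
* The ANCOVA operates on per-timepoint medians (2T observations), so its
  residual degrees of freedom are T − 2; with very short timecourses the
  interaction test has limited power.
* The intron-evolution model is a star phylogeny with independent per-intron
  walks; it produces the neutral-vs-constrained contrast the conservation
  statistics need, not a realistic correlated phylogenetic process.
* Abortive degradation at mitosis is instantaneous; if partial persistence of
  aborted fragments matters, `abort_prob_at_mitosis` < 1 is the only lever.
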