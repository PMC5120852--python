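# Methods

## Data model and conventions

Internally every genomic position is 0-based; the Bismark-coverage dialect
(1-based inclusive) and the per-read TSV are converted at the I/O boundary
only. Features are 0-based half-open intervals; a CpG belongs to a feature
iff `start <= pos < end`. Plus- and minus-strand calls of a CpG dyad are
kept as separate sites by default, mirroring raw Bismark coverage output; an
optional collapse merges `pos`/`pos+1` pairs by summing counts. The
methylation level of a site is `m = n_meth / (n_meth + n_unmeth)`; of a read,
`r = (# methylated CpGs) / (# CpGs on the read)`.

## Coverage and CpG-count gates

* A CpG is analyzable only with ≥5 covering reads; with the all-sample flag
  (the default in the pipeline) a site must pass in **every** sample, so the
  analysis set is the intersection. The per-sample threshold is applied
  before intersecting.
* Promoters and ICRs contribute a region mean only with ≥5 qualifying CpGs;
  L1 subfamilies are summarised only with ≥500 qualifying CpGs; an
  under-covered feature is reported as undefined (NaN), never as zero.
* Read-level analysis uses reads with ≥5 CpGs and regions with ≥20 such
  reads.

All gates are boundary-inclusive. The differential effect gate compares the
computed `delta_max` against the threshold with a 1e-12 absolute tolerance
so that group means assembled by floating-point arithmetic cannot fall just
under an exactly-attained boundary.

## Aggregation semantics

Per-site levels are averaged **unweighted** (not coverage-weighted) within
features and feature classes, because the unit of analysis is the CpG
cytosine, not the read. Class summaries are computed per sample first
(pooling CpGs genome-wide within the class), then summarised across the
samples of each age group as mean ± SE (sample SD / √n_g). An alternative —
averaging per element before pooling — would weight small elements more; the
pooled-CpG form was chosen because class-level tables are naturally
statements about CpGs of that class. Region means for promoters/ICRs are
per-region averages of site levels, which is what the differential test
consumes.

The metaplot rescales each gene body to 40 bins with 2 kb flanks in 20 bins
each (bin counts are a presentation choice; any smooth desk-scale profile
works). Minus-strand genes are orientation-flipped; a bin's value is the
mean of site levels in it, averaged across genes, then across samples.
Genes shorter than the body-bin count are skipped and counted.

## Differential testing

Welch's one-way ANOVA is used because group variances differ strongly in
this design (nearly-zero variance at unmethylated promoters in some groups,
and unbalanced group sizes 7/3/7). Implementation follows the classical
formulas (variance-weighted means, adjusted denominator df); it matches
pingouin's `welch_anova` and R's `oneway.test` to machine precision (tested).
A group whose sample variance is exactly zero (all samples identical, common
at fully unmethylated promoters) gets a variance floor of 1e-6 and the
result is flagged; the statistic is otherwise undefined there.

Benjamini–Hochberg correction is the standard step-up with enforced
monotonicity and stable tie-breaking on (p, input index). It is applied to
**all testable regions** (every group retaining ≥2 values) *before* the ≥5%
effect gate, because both conditions define the differential set jointly and
the BH denominator should reflect the full family of tests. "Significant"
means adjusted q < α; a raw-p mode exists behind a flag for comparison.

Games–Howell post-hoc comparisons use the studentized-range distribution
with Welch–Satterthwaite degrees of freedom. Tail probabilities come from
scipy's `studentized_range` (validated against the classical table value
q ≈ 3.88 at k=3, df=10, α=0.05); at k=2 the distribution reduces exactly to
√2·|t|, so the two-sided t tail is used directly there — numerically exact
rather than quadrature-limited. The compact-letter display uses the
insert-and-absorb algorithm: start with all groups in one letter, split on
each significant pair, absorb subsets; groups share a letter iff not
significantly different, deterministically given group order.

Cluster labelling: differential regions' sample vectors are z-scored (mean
0, SD 1 across samples; flat vectors are excluded and reported), clustered
agglomeratively with average linkage on Euclidean distances, and the tree is
cut at k=2. The cluster whose mean z in the reference (youngest) group
exceeds its mean z elsewhere is cluster I. Linkage and metric are recorded
in the run manifest and swappable in the config.

Known behavior worth stating: with the smallest group (n=3) carrying the
largest variance, Welch's test is mildly liberal — its true null rejection
rate at α=0.05 in the 7/3/7, SD (1,3,1) configuration is ≈0.07–0.08 rather
than 0.05 (confirmed against R's `oneway.test` by Monte Carlo). This is a
property of the statistic, not of this implementation.

## Read-level analysis

Bins for read-level methylation r are left-closed with a closed top bin:
[0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1]. The outer bins are pinned
by the ">80% methylated" / "<20% methylated" read classes; interior edges
follow the same convention, so r = 0.6 falls in the fourth bin and r = 0.8
in the top bin.

The pattern call uses two thresholds on the bin shape: pattern I requires a
top-bin fraction ≥ tau_high with middle-bin mass ≤ tau_mid; pattern II the
reverse. Defaults tau_high = tau_mid = 0.05 separate the two mean-matched
generators cleanly at realistic depths and are mandatory, recorded config
entries in pipeline runs. The epiallele-fraction estimator is the top-bin
fraction with a Wilson 95% interval; with 5–10-CpG reads it is attenuated
relative to the molecular fraction because a fully methylated molecule's
read can sample below the bin edge (the closed-form attenuation under the
binomial model is what the tests check against).

The contamination filter drops reads with r ≥ 0.6 (inclusive, matching the
"≥60% methylated" read class) and recomputes the region level as the pooled
per-CpG mean over surviving reads — methylated observations over total
observations, identical to the CpG-count-weighted mean of read levels and
consistent with the site-level definition. Recomputation is per sample, with
group summaries taken afterwards (per-sample recomputation composes with the
mean ± SE machinery; pooling reads across samples first would hide
sample-to-sample variation).

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: three age
groups of 7, 3 and 7 samples; hypomethylated promoters/ICRs (per-CpG ≈2%)
with a rho = 0.10 fully-methylated epiallele admixture in the youngest group
only; repeat classes with high means and a small monotone age trend (LINE
80/82/83.1%, plus LTR, SINE, one ≥500-CpG L1 subfamily, exon/intron/
intergenic classes); ≈30× per-CpG coverage; reads carrying 5–10 CpGs
(uniform); 0.5% conversion-failure noise (conversion >99%). rho = 0.10 was
chosen so that the observable top-bin read fraction lands in the 5–15%
window reported for such regions; the true molecular fraction is not itself
an observable the generator asserts.

Key construction choices:

* **Epiallele state is drawn once per read** in mixture mode — this is what
  creates the bimodal read distribution; uniform mode draws every CpG at the
  pooled mean, so the two modes are mean-matched by construction and only
  read-level statistics separate them.
* **Coverage tables are aggregated exactly from the emitted reads**, so
  conservation between the read-level and site-level representations is an
  identity, not an approximation.
* **RNG streams are keyed by (seed, sample index, region index)** so
  generation is reproducible and order-independent.
* Coordinates are emitted 1-based in the coverage/read TSVs and 0-based
  half-open in BED, matching each format's convention.

What the generator does **not** emulate: sequence-level reads, MspI fragment
selection and its coverage biases, alignment or mapping error, non-CpG
methylation, spatially correlated methylation along a region beyond the
two-class mixture, and biological between-sample variability beyond binomial
sampling. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated mixture model, not robustness to alignment
artifacts or unmodelled overdispersion in real libraries.

## Problem sizes

The default design uses 75 regions (≈1,650 analyzable CpGs, ≈116k reads
across 17 samples), chosen to exercise every gate and code path while
keeping a full pipeline run in seconds. Simulation-based checks use 2,000
null replicates for error-control estimates, 50×500 reads for estimator
recovery, 100 replicates per arm for pattern discrimination, and 20 seeds
for power/FDR — sizes at which Monte-Carlo error is small relative to the
asserted tolerances.

## Limitations

* The variance floor makes p-values at exactly-constant regions
  conservative rather than undefined; flagged in output.
* The pattern call is threshold-based, not model-based; a likelihood-ratio
  classifier would use more of the bin shape but would tie the call to the
  generator's parametric form.
* Welch/Games–Howell calibration degrades with very small, high-variance
  groups (see above); with n=3 in one group, post-hoc p-values near α
  should be read cautiously.
* The epiallele-fraction estimator is attenuated for short reads; no
  deconvolution is attempted.
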