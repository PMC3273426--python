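# Methods

## The model

`glmseq` analyses differential expression between two conditions
(e.g. a pesticide-resistant and a pesticide-susceptible insect strain)
when the four RNA-Seq libraries were prepared in two batches, one
replicate pair per batch.  For each contig the data are a *quartet* of
un-normalized read counts y = (y_r1, y_s1, y_r2, y_s2), modelled as
independent Poisson variates with a log-linear mean and a fixed offset
equal to the log library size N_ij:

    log E[y_ij] = log N_ij + alpha + beta*[batch 2] + gamma*[resistant]
                  + delta*[batch 2 & resistant]

Treatment (reference-cell) coding is used with (batch 1, susceptible)
as the reference.  gamma is the main condition effect on the natural-log
scale; exp(gamma) is the resistant/susceptible fold change; delta is a
contig-specific batch-by-condition interaction.  The model is
*saturated* — four parameters, four observations — so:

- the MLEs are closed-form offset-adjusted log count ratios, e.g.
  `gamma = log((y_r1/n_r1) / (y_s1/n_s1))`;
- fitted means equal the observed counts (residual deviance 0);
- the Wald standard error comes from the Poisson information,
  `SE(gamma) = sqrt(1/y_r1 + 1/y_s1)`, not from a residual variance;
- gamma, its SE and p-value depend only on the batch-1 cells: the
  interaction absorbs any batch-2 disparity.  This is the method's
  point — a contig whose batch-2 counts differ wildly while batch-1
  counts agree is *not* called differentially expressed.

Significance is a two-sided standard-normal Wald test,
`p = 2*(1 - Phi(|gamma/SE|))`.  No pooling, shrinkage or
pseudo-reference normalization is applied across contigs: each quartet
is fit independently, and library-size offsets are the only
normalization.

The same model is fit two ways: by the closed form
(`fit_quartet_closed_form`, the production path) and by iteratively
reweighted least squares (`fit_quartet_irls`).  IRLS starts at
mu = y + 0.5 (deliberately *not* at the closed form, which would make
the two routes trivially identical), converges on the change in
deviance (tolerance 1e-8, at most 50 iterations), and serves as an
internal oracle; the test suite additionally cross-checks both against
statsmodels' Poisson GLM.

### Zero counts

A saturated log-linear model has no finite MLE when a cell is zero.
The default policy (`zero_policy="haldane"`) adds the Haldane–Anscombe
continuity correction of 0.5 to **all four** cells before the closed
form and flags the fit `corrected=True`; a `strict` policy raises
instead.  A quartet whose batch-1 row is entirely zero carries no
information about the main effect and is reported `estimable=False`
with p = 1.  Note the correction is quartet-global, so a zero in a
batch-2 cell perturbs gamma slightly; the batch-1 locality property
holds exactly for strictly positive quartets.

### Library sizes

Offsets are a required user input (total reads per library).  The
bundled deep-sequencing preset (6.3e7, 7.2e7, 6.2e7, 7.2e7 for
r1, s1, r2, s2) is the post-quality-trimming read-total set under which
the package's two reference worked examples reproduce their printed
fold changes and p-values.  By offset-scale invariance, only ratios of
library sizes matter.

## Ranking and selection

Fits are ranked by ascending p, ties broken by descending ALFCA
(absolute log2 fold change, adjusted in the sense of library-size
offsets: `|gamma/ln 2|`), then lexicographic contig id — a total,
permutation-invariant order.  `select_top_k` takes the prefix;
`count_significant` uses a strict `p < alpha` cut with default
alpha = 0.005.  Direction (up/down) is the sign of gamma.
Non-estimable fits (p = 1, ALFCA undefined) sort last.

## Unique-expression screen

Counts from two biological replicates per condition are scaled per
sample by (mean library size / library size) — a deliberately simple
depth normalization; no length or GC correction is attempted.  A
condition is called `not_expressed` when **both** replicates' scaled
counts are strictly below 10, `expressed` when both are strictly above
100, otherwise `indeterminate`.  A contig is unique to a condition iff
that condition is expressed and the other is not expressed; the middle
band never produces unique calls.  Thresholds are configurable.

## GO enrichment

A test set (typically the up- or down-regulated half of the top-k) is
compared against a reference set (all annotated contigs outside the
test group).  The universe is restricted to annotated contigs;
overlapping inputs are disjoined by removing test members from the
reference (with a warning).  Per term, a 2x2 table is tested with the
two-tailed Fisher's exact test under the minimum-likelihood rule: the
p-value sums the hypergeometric point probabilities of all tables with
the observed margins whose probability does not exceed the observed
one (ties compared with a 1e-7 log-scale tolerance; degenerate margins
give p = 1).  Terms absent from both sets are skipped so the
Benjamini–Hochberg denominator counts only testable hypotheses.
Adjusted q-values are BH step-up (via statsmodels); terms with
q < 0.05 (configurable) are reported, with direction `over` when the
test-set proportion exceeds the reference proportion.  No GO-graph
ancestor propagation is performed.

## Assembly QC

- **N50**: sort contig lengths descending and accumulate; N50 is the
  length at which the running sum first reaches half the total.  It is
  always a member of the length set and is invariant under duplicating
  every length.
- **Ortholog hit ratio (OHR)**: for each query contig, the best
  alignment (highest bitscore, ties by lowest e-value then subject id)
  against a putative ortholog; OHR = aligned subject span / subject
  length, clamped to [0, 1] with a warning if coordinates exceed the
  subject.  Span is `abs(send - sstart) + 1` from 12-column BLAST
  tabular input (minus-strand hits report descending subject
  coordinates); overlapping HSPs are not merged — only the single best
  HSP counts.  `ohr_distribution` bins per-query OHRs into deciles and
  reports the strict fractions above 0.8 and 0.5.

## Synthetic data

The generator draws exactly from the model's own assumptions: cell
means `mu = N_cell * exp(b + beta*[batch2] + gamma*[res] + delta*[both]) / mean(N)`,
counts Poisson(mu).  Scaling by mean(N) makes the baseline `b`
interpretable as the log expected count in an average-depth library
(any fixed scaling is equivalent by offset invariance).  Defaults,
chosen once as a realistic deep paired-batch insect RNA-Seq study:

| parameter | default | rationale |
|---|---|---|
| library sizes | 6.3e7, 7.2e7, 6.2e7, 7.2e7 | the reference study's post-trimming depths |
| de_fraction | 0.3 | roughly the significant fraction in such a study (~15k of ~51k contigs) |
| baseline log-mean | Normal(5.0, 1.5) | median ~150 counts/contig with a long right tail, consistent with ~6e7 reads over ~5e4 contigs |
| gamma (DE contigs) | Normal(0, 1) | fold changes mostly within ~e^±2 |
| delta (DE contigs) | Normal(0, 0.5) | interactions weaker than main effects |
| batch_effect | 0.2 | residual batch shift beyond depth |

Non-DE contigs have gamma = delta = 0 exactly, so ground truth
satisfies `is_de ⇔ gamma != 0`.  An optional negative-binomial mode
(gamma-Poisson mixture with size parameter `dispersion`) adds
overdispersion for robustness experiments; it is *beyond* the Poisson
model and off by default.  The GO-universe generator assigns each term
independently per gene with a term-specific background probability and
multiplies that probability (capped at 1) inside a designated subset
for planted terms.

All randomness flows through one `numpy.random.default_rng(seed)`, so
outputs are bit-reproducible across platforms.

**What passing tests show — and don't.**  The generator matches the
model, so calibration and recovery results (type-I error ≈ nominal,
unbiased gamma-hat at high counts) validate the inference machinery,
not the Poisson adequacy of real RNA-Seq data, which is typically
overdispersed across biological replicates.  Here the two "replicates"
are batches modelled with explicit batch and interaction terms, which
is precisely the design the method targets; users should still expect
anti-conservative p-values if extra-Poisson variation exists within a
batch.  The generator also produces no length/GC biases and no
assembly artifacts.

## Problem sizes used in the checks

The bundled verification runs use 10,000 null quartets for
calibration, 2,000 contigs for parameter recovery, 1,000 random
quartets for the closed-form/IRLS sweep, and the exhaustive Fisher
enumeration over all 2x2 tables with row margins ≤ 30 — sizes at which
the Monte-Carlo error bounds quoted in the tests are meaningful while
the whole suite runs in well under a minute per check.

## Numerical choices

- Wald p-values use `scipy.stats.norm.sf`; fold change is
  `exp(gamma)` exactly, ALFCA `|gamma|/ln 2` exactly.
- Floats are serialized with `repr` precision, so write-then-read
  round trips are bit-exact and pipeline reruns are byte-identical on
  the data artifacts (the run log carries wall-clock timings and is
  excluded).
- Fisher point probabilities are computed with `scipy.special.gammaln`
  on the hypergeometric support; the test suite verifies them against
  exact rational enumeration.
- Ranking tie-breaks and id-sorted output files make every artifact
  deterministic under input permutation.

## Known limitations

- Poisson only: no dispersion estimation or negative-binomial test; a
  quartet design cannot estimate within-batch biological variance.
- 2x2 designs only (two conditions, two batches).
- The unique-expression screen's depth scaling is not a length/GC
  normalization; calls on strongly length-biased libraries will drift.
- GO enrichment tests terms independently, without the GO DAG.
- OHR uses a single best HSP; fragmented alignments of a truly
  full-length contig under-estimate completeness.
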