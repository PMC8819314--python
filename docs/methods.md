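# Methods

This note records the statistical procedures implemented in `mesokit`, the
defaults they use, the modeling choices made where the published workflow
left the construction open, and what the synthetic-data tests do and do not
demonstrate.

## Copy-number scoring and patient stratification

Segment tables carry one value per genomic segment per sample, either on a
relative z-like scale (cohort GISTIC-style data; 0 ≈ neutral) or as absolute
copy number (cell-line arrays).  A gene locus or chromosome arm is scored as
the **overlap-length-weighted mean** of the segment values covering it;
an alternative maximum-magnitude aggregation is available behind
`method="max_magnitude"`.  A region with no overlapping segment scores NaN,
which is deliberately distinct from 0 and always classifies as unaltered.

Classification uses four z decision lines — low gain 0.1, high gain 0.3,
low loss −0.1, deep loss −0.3 — with **strict** inequalities on both sides
(a locus at exactly z = 0.3 is a low gain, not a high gain).  Cell-line
absolute copy numbers classify as amplified above 2.3 and lost below 1.7,
again strictly.

A gene is called altered by any of: (a) a mutation record, (b) its locus
classifying high-gain (for gain-direction genes, i.e. KRAS at
chr12:25,357,180–25,404,863) or deep-loss (loss-direction, TP53 at
chr17:7,570,720–7,591,868), or (c) its arm score crossing the *low* line in
the gene's direction (12p gain / 17p loss).  The arm criterion is a
documented local choice: the source workflow counts arm events without
printing an arm threshold, and 0.1 is the printed "low" line.  Evidence from
every contributing source is retained on each call.  Stratification is then
purely Boolean: KRAS∧TP53 → dual stratum, KRAS alone → KRAS-only, anything
else (including TP53-only) → other.

Coordinates are 1-based inclusive externally (the convention of SEG files
and of the printed loci) and 0-based half-open internally; the converters
are integer-exact.  Chromosome names with and without the `chr` prefix are
accepted.  The GRCh37 arm table is bundled (standard chromosome lengths and
centromere boundaries; p = 1..centromere start, q = centromere end+1..chromosome
end).

## ddPCR gating and quantification

Droplet amplitudes are gated at fixed thresholds (wild-type 6,000, mutant
10,000, TP53 5,500, TERT 7,000 fluorescence units).  A droplet above both
gates counts in **both** positive classes: the quantification formulas are
ratios of per-class positive counts, not of mutually exclusive quadrants.
Mutant copy % = 100·n_mut⁺/(n_mut⁺+n_wt⁺) with a Clopper–Pearson exact 95%
CI on the binomial proportion; TP53 copies % = 100·n_TP53⁺/n_TERT⁺ with
TERT as a two-copy reference (100% ≈ diploid).  Zero positives of both
classes yield an *undefined* (NaN) estimate rather than 0%.  No Poisson
volume correction is applied — the published quantities are droplet-count
ratios, and concentration estimation is out of scope.

Patient calling: KRAS-altered on ≥1 mutant-positive droplet in any well of
any sample; TP53-altered when any sample's TP53 % leaves the normal range.
The normal range is configuration-driven with default **[80%, 120%]**: the
published plots mark the limits without printing values, so the default was
fixed once from the spread of simulated diploid control wells.

## Survival

Kaplan–Meier survival is the product-limit estimator; pointwise 95% bands
use the Greenwood variance on the log(−log S) scale; the median is the
earliest event time with S(t) ≤ 0.5 and its CI is where the band crosses
0.5 (Brookmeyer–Crowley).  The log-rank (Mantel–Cox) test is the k-sample
observed-minus-expected construction over distinct event times with the
hypergeometric (ties-aware) variance–covariance.

The hazard ratio is the classical **Mantel–Haenszel pooled rate ratio**
over the 2×2 risk-set tables at each event time, HR = Σ(d₁ⱼn₂ⱼ/nⱼ) /
Σ(d₂ⱼn₁ⱼ/nⱼ), with the Greenland–Robins variance for the CI.  The
Peto-type approximation exp((O₁−E₁)/V) is reported alongside (`hr_peto`)
but is not the primary estimate: it is biased away from the null for
hazard ratios far from 1 (in simulation at HR = 3 with 200 events per
group its median estimate is ≈ 3.3, versus ≈ 3.0 for the pooled rate
ratio).  Fully separated groups make the pooled ratio degenerate (0 or
infinite); such results are flagged undefined.

## Substitution spectra, co-occurrence, instability

Single-nucleotide substitutions are collapsed to the six pyrimidine-strand
classes (C>A, C>G, C>T, T>A, T>C, T>G); purine-reference records are
reverse-complemented; indels are skipped and counted; ref = alt records are
rejected.  Spectrum counts plus skips plus rejections always equal the
input record count.

Co-occurrence of two binary alteration vectors is tested against the
hypergeometric null with observed margins.  The primary output is the
one-sided enrichment p, P(overlap ≥ k); the two-sided p uses the
point-probability method (sum of all outcome probabilities ≤ the observed
one).  Degenerate margins return p = 1 with a flag.

The instability indices are **reconstructions** — the source cohort plots
precomputed indices without formulas, and outputs are labeled accordingly.
Genome-altered fraction = length-weighted fraction of the covered genome
with |z| > 0.1; aneuploidy score = number of arms whose length-weighted
score magnitude exceeds 0.1.  These may differ from the original
consortium definitions.

## Expression signature and bi-clustering

The published cohort reports 40 genes "significantly overexpressed" across
the three strata without naming the test.  The implemented criterion —
per-gene Kruskal–Wallis across the three strata, Benjamini–Hochberg
correction over genes, and a conjunctive strict median ordering
median(dual) > median(KRAS-only) > median(other), default q ≤ 0.05 — is a
documented reconstruction consistent with the cohort's pervasive use of
Kruskal–Wallis and FDR.  Because it is rank-based with a median-ordering
gate, the signature is invariant to any monotone per-gene transformation of
the expression values.  Results on the real cohort may differ from the
published 40-gene list; reproducing that list is a non-goal.

Bi-clustering uses distance d = 1 − Pearson r and complete linkage (scipy),
whose merge heights are monotone non-decreasing; ties break by input order.
Constant rows/columns are rejected (correlation undefined) for clustering
and dropped with a warning for z-scoring (population sd).  Dendrograms
export to Newick with branch lengths from merge heights.  Cluster
enrichment of altered patients in a chosen cluster is an upper-tail
hypergeometric test.  qPCR relative abundance is 2^−(Ct_target − Ct_ref).

## RNA-seq cascade

The order is: (0) remove genes with zero counts in all samples; (1)
median-of-ratios size factors — for each gene positive in every sample,
the ratio of each sample's count to the gene's geometric mean; the factor
is the per-sample median of those ratios (defined up to a common constant);
(2) three filters removing the union of their catches, with strict
inequalities so a gene exactly at a cutoff is kept:

* length < 500 bp;
* average reads per 100 bp — mean over samples of normalized count ×
  100/length — *less than* the 25th percentile of that distribution;
* mean normalized count *below* the median of per-gene mean normalized
  counts.

"Average reads per 100 bp" and "per-gene mean vs the median of that
distribution" are documented readings of wording that admits alternatives
(per-gene totals would be another).  Cutoffs are computed from the input
distribution by default but can be passed explicitly; re-running the filter
on its own kept set with the realized cutoffs removes nothing, whereas
recomputing quantiles on the survivors would necessarily remove more (the
25th percentile of survivors is ≥ the original cutoff by construction).

Differential expression is a per-gene conditional negative-binomial exact
test, written here rather than wrapped: group sums (on the normalized
scale) are compared under a null of a shared mean, enumerating every split
of the observed total and summing joint probabilities not exceeding the
observed one.  Dispersion is method-of-moments within groups, pooled across
groups, and **floored at the across-gene median** estimate — with 3
replicates per group the raw per-gene estimator is noisy and
anti-conservative when it undershoots; the floor restores null calibration
(rejection rate ≤ α + 2·SE in simulation) at no measurable cost to the
recovery of 4-fold planted changes.  With a single replicate per group the
two samples are pooled as pseudo-replicates, as in early count-model
practice.  A gene is DE iff BH q ≤ 0.05 **and** the normalized-mean ratio
with pseudo-count 1 is ≥ 2 in either direction; significant genes partition
exactly into up and down.

## Enrichment

The pre-ranked enrichment score walks the descending ranked list; hits add
|score|^p normalized over in-set scores (weight p = 1, the classic
pre-ranked default; configurable), misses subtract 1/(N − N_hits); ES is
the signed maximum deviation, bounded in [−1, 1] and invariant to positive
rescaling of the scores.  The nominal p permutes gene labels (the only
scheme available for pre-ranked input) and is sign-conditional, as in the
original method.  Overrepresentation of a query list in annotation sets
uses an upper-tail binomial p with success probability |set∩ref|/|ref| and
|query| trials, fold-enrichment = observed/expected, and BH q across sets.

## Synthetic data: what it emulates and what it does not

The cohort generator's defaults are the reference human cohort's
conditions: 86 patients — 69 unaltered, 10 KRAS-only, 7 KRAS+TP53.  Each
altered patient receives either a mutation record (probability ½) or a
planted focal event at the relevant locus (z = +0.5 for KRAS, −0.5 for
TP53); unaltered patients receive neither, plus a C>T-skewed background
spectrum (weight 5 on C>T vs 1 on the other five classes) reproducing the
C>T preponderance of unaltered tumors.  Altered patients carry 2 (KRAS-only)
or 4 (dual) additional whole-arm events at |z| = 0.2 on arms other than
12p/17p, giving them higher instability indices.  Per-arm baseline noise is
Normal(0, sd 0.05) — the variance structure of real segment z-scores is not
published, so this is a modeling choice — truncated to |z| < 0.095 so that
no unplanted arm can cross the ±0.1 low lines and the planted strata remain
exactly recoverable.  Forty signature genes have group means stepped by 3.0
(in log2-expression units) across the strata over noise sd 1.0; 160
background genes are flat.  Survival is exponential with scale 780 days
(median ≈ 540 days) for unaltered patients and hazard multipliers 2 and 3
for the KRAS-only and dual strata (the published cohort shows worse
prognosis without printing a hazard ratio; the values here are plausible
for the reported separation), administratively censored at 5 years.

Droplet wells are mixtures of empty, wild-type, and mutant axis-aligned
Gaussian clouds (defaults: negative at (2,000, 2,000), wild-type at
(2,000, 9,000), mutant at (13,000, 2,000), sd 300; occupancy 0.7), many
standard deviations clear of the gates, so gated counts equal generated
class labels exactly; a uniform "rain" component is opt-in.  TP53/TERT
wells draw channel positives independently with P(TERT⁺) = occupancy and
P(TP53⁺) = occupancy × planted ratio.  Count matrices are negative
binomial with var = μ + αμ² (default dispersion 0.05), planted fold
changes alternating up/down, per-group or per-sample library-size factors,
and configurable fractions of sub-500-bp and all-zero genes.

Passing tests on these data show that the estimators recover *cleanly
separable* planted truth under the model's own assumptions.  They do not
show robustness to the things real data add: segment boundary noise and
focal events overlapping loci partially, ddPCR rain and drifting clouds,
batch effects and GC/length biases in counts, non-proportional hazards, or
dependence between genes.  All randomness flows through one explicit numpy
Generator; identical seeds give byte-identical files.

## Problem sizes used in the checks

The automated checks use: a 90-patient cohort (30 per stratum) for exact
stratification recovery; 1,000 wells of 20,000 droplets at a planted 5%
mutant fraction for CI coverage; exhaustive enumeration up to N = 12 for
the hypergeometric and binomial oracles; 200 repeats of 200-events-per-group
exponential simulations for hazard-ratio recovery; 100 random 5–8-item
instances against an O(n³) clustering oracle; a 500-gene fixture (40 DE at
|FC| = 4, 10% short, 10% all-zero, planted 2× library ratio) for the RNA-seq
cascade; and 1,000 random gene sets for enrichment-score calibration
(Kolmogorov–Smirnov distance < 0.05 from uniform).

## Known limitations

* The arm-level calling criterion, the TP53 normal range, the DE test, and
  the signature criterion are documented reconstructions where the source
  left the construction unstated; each is configurable.
* The instability indices are local definitions and not comparable in
  absolute value to consortium-published indices.
* The DE exact test enumerates the observed total per gene; extremely deep
  counts (group totals ≫ 10⁵) would be slow and would warrant a normal
  approximation, which is not implemented.
* Multivariable survival models (Cox), 96-class trinucleotide signatures,
  phenotype-permutation GSEA, and raw array/read processing are out of
  scope.
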