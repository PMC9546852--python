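# Methods

This note documents the statistical models, numerical choices and known
limitations of `chemosig`. It is written for users deciding whether the
defaults suit their data and for maintainers revisiting design decisions.

## Mutation catalogs and clonal filtering

Somatic calls are consumed as per-clone VCFs (pysam) or pre-tabulated TSV
records; the pipeline deliberately starts downstream of alignment, variant
calling and copy-number/purity estimation. Clonal filtering keeps calls
with VAF **strictly greater than 0.30** — in a clonally expanded ASC
organoid, founder-cell heterozygous mutations sit near VAF 0.5, while
mutations acquired in culture after the single-cell step sit below ~0.3 —
and restricts to autosomes (chromosome names are normalised by stripping a
`chr` prefix). The boundary value 0.30 itself is excluded. Burden is the
filtered autosomal count per mutation type. Doublet substitutions are
taken as emitted by the upstream caller (2-bp records); no merging of
adjacent single-base records is attempted.

Channel classification follows the standard schemes:

* **SBS96** — pyrimidine-strand trinucleotide contexts, labels like
  `A[C>T]G`. Purine-reference calls are reverse-complemented with flanks
  swapped and complemented. Flanks come from a pre-annotated `context`
  column or from a faidx-indexed FASTA.
* **DBS78** — reverse-complement collapse onto the 10 canonical reference
  doublets. Both positions must change; single-position "doublets" are
  rejected as upstream mislabels.
* **ID83** — indel type x length x repeat-unit count, with microhomology
  classes for repeat-free deletions ≥ 2 bp. Repeat units are counted
  contiguously on both sides of the event; microhomology is the longest
  flanking match of the deleted sequence's prefix (right) or suffix
  (left). The classifier raises rather than guesses when a repeat run is
  truncated by the supplied window before the 6-unit class cap.

Structural variants use LINX-style annotations: *simple* events are
single-member clusters resolved as DEL/DUP, binned half-open on length
with a sub-kilobase bin `[50 bp, 1 kb)` ahead of the conventional decade
bins (the radiation signal concentrates in 50 bp–10 kb deletions);
*complex* events (multi-member clusters, reciprocal inversions and
translocations, complex deletions) count once per cluster. SV load is the
number of simple events.

## The aging null and the excess-burden test

Burden vs. age on untreated clones is a linear mixed model with fixed
intercept and age slope and a per-donor random intercept, fitted by REML
(statsmodels MixedLM; optimizer fallbacks lbfgs → cg → powell; Wald 95%
CI on the slope). Noise-free inputs, where REML is degenerate, short-cut
to the exact least-squares line with zero variance components. Random
slopes are not fitted — with 1–6 clones per donor they are not
identifiable.

The null distribution of expected burden is built by refitting the model
on `B` random 70% subsamples (without replacement, sample-level) of the
untreated clones and recording, for every integer age 5–80, the
**predictive** burden of a new untreated clone: the fixed-effect line plus
one donor random-effect draw and one residual draw from the refit's
variance components. Recording only the fixed-effect line is available
(`predictive=False`) but is sharply anticonservative on cohorts of this
size: the line's bootstrap spread (tens of mutations) is far smaller than
the donor-level scatter a tested donor actually exhibits (~130 mutations
at the default variance components), which on simulated aging-only donors
yields a measured type-I error near 0.5 at nominal 0.01. The predictive
null uses one clone's residual rather than the tested donor's clone
count, making it calibrated-to-conservative for multi-clone donors
(measured type-I error 0.00–0.03 at nominal 0.01; power for a
+1650-mutation donor-level excess at age 24 ≈ 1.0).

A treated donor's test statistic is its mean clone burden at its age
rounded to the integer grid (no extrapolation outside 5–80). The
one-sided empirical p is add-one smoothed,
`p = (1 + #{draws ≥ observed}) / (B + 1)`, so it is never zero and
recovers the raw proportion as B grows. Non-converging bootstrap refits
are dropped and logged (warning above a 10% drop rate). Defaults:
B = 10,000, fraction 0.70; the test suite and acceptance script use
B = 1,000, which leaves the p-value resolution (10⁻³) far below the 0.01
decision threshold.

## Signature extraction and strict refitting

De novo extraction is non-negative matrix factorisation under the
generalised Kullback–Leibler divergence — the Poisson-flavoured objective
appropriate for count catalogs — via multiplicative updates
(scikit-learn's `mu` solver), tolerance 1e-6, at most 2000 updates, best
of `n_restarts` random initialisations (default 100). A Frobenius
objective is available as a config alternative. Signature columns are
normalised to probability profiles with contributions rescaled so the
reconstruction is unchanged; fixed seeds give bitwise-reproducible
results. Rank selection extracts at each candidate rank and greedily
matches de novo profiles 1:1 to reference profiles by cosine; the chosen
rank is the largest at which every de novo signature reaches cosine ≥ 0.8
to some reference. Sub-threshold profiles are reported as `novel` rather
than hidden — in treated cohorts these are the candidate therapy
signatures (a blend of the 5-FU and platinum profiles matches neither
aging reference alone).

Strict refitting attributes a sample's catalog to a small constrained set:
aging signatures (SBS1/5/18; DBS2/4/6/9/11; ID1/2/5) plus therapy
signatures (5-FU SBS17 with 17a+17b merged by renormalised sum, platinum
SBS35 and DBS5, colibactin SBS88/ID18, radiation ID8). A signature enters
the set only if its matched de novo contribution reaches 10% in at least
one sample; therapy signatures are always retained for treated cohorts.
The refit itself is NNLS followed by greedy backward elimination: per
round, the signature whose removal least decreases the reconstruction
cosine is dropped while that decrease stays below `max_delta = 0.004`;
survivors get a final NNLS. With `max_delta = 0` this is plain NNLS
(verified against an exhaustive grid-search oracle). Exposures are
non-negative, scale-equivariant counts; relative contributions divide by
the sample's burden of that type.

**Detection limit.** Eliminating a near-orthogonal signature contributing
a fraction *f* of a catalog lowers the reconstruction cosine by roughly
f²/2, so the default `max_delta` implies a detection floor near 9% of the
catalog. Consequences under the default study conditions: a 105-mutation
platinum load from a single chemotherapy cycle on a 2000–3500-mutation
aging background is frequently attributed zero. Attribution zeros are
censoring, not absence of exposure; dose–response and ratio estimates
therefore condition on clones with detected platinum activity
(SBS35 > 0). Measured on pooled replicate cohorts, the all-clone
per-cycle slope inflates to ~130 while the detected-only estimate centres
on the configured 105.

## Treatment-effect estimation

* **Dose–response**: exposure ~ cycles with donor random intercept
  (REML); two-tailed t on the slope with `n − 2` residual degrees of
  freedom (the Satterthwaite approximation would be an alternative; with
  these cohort sizes the difference is immaterial next to sampling
  noise).
* **SBS:DBS coupling**: ordinary least squares of DBS on SBS with
  intercept; the headline ratio is the inverted slope with a delta-method
  SE, reported alongside Pearson's r.
* **Aging rates**: the burden mixed model applied to summed aging
  signature exposures (SBS1+SBS5+SBS18), comparable across treated and
  untreated groups.
* **Group contrasts**: one-sided Wilcoxon rank-sum (exact enumeration for
  tie-free groups with min(n,m) ≤ 10, otherwise normal approximation with
  tie correction). Significance convention is p < 0.01, reported raw with
  no multiple-testing correction anywhere, matching the single-figure
  scale of the analyses.
* **Correlations**: product-moment r with Fisher-z 95% interval.

## The synthetic cohort generator

The generator's defaults encode the study conditions the pipeline
targets; every parameter is overridable but the defaults are fixed:

| process | law | default |
|---|---|---|
| aging SBS | Normal(intercept + rate·age + donor effect, residual sd), truncated at 0, rounded | 100 + 43/yr, donor sd 100, residual sd 150 |
| platinum SBS | Normal(105·cycles, 33·√cycles) | cycles uniform 1–6 per treated donor |
| platinum DBS | Binomial thinning of platinum SBS | 1/26 per SBS |
| 5-FU SBS | per-clone Bernoulli(0.3) × Normal(265, 195) | all-or-none activation |
| radiation ID8 | Normal(80, 15) for irradiated donors (2 of 6 treated) | |
| radiation deletions | Poisson(0.18 · ID8), log-uniform 50 bp–10 kb, microhomology 0 | plus ~2 complex clusters per irradiated clone |
| background DBS / indels | Poisson(0.25/yr), Poisson(2.5/yr) | aging DBS/ID mixtures |
| VAF | clonal Beta(60, 60); subclonal Beta(4, 26) | 50 in-vitro subclonal SBS per clone |

Counts for the headline processes use truncated-rounded Normals rather
than Poissons so the configured standard deviations (overdispersed
relative to Poisson) are matched; small background processes are Poisson.
5-FU activation is drawn per clone, not per donor, reproducing both
inter- and intra-donor heterogeneity. Channels are drawn multinomially
from each process's signature profile, and the realised per-process
counts are recorded exactly in the ground-truth table. Cohort sizes
default to 12 untreated donors × 3 clones and 6 treated donors × 4
clones. Written cohorts (TSV or per-clone VCF 4.2 with `AF`, `TNC`, `IDC`
INFO fields) round-trip losslessly through the catalog readers.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: sequencing and calling error, coverage
bias, copy-number-altered regions, mutational-process interactions,
lesion segregation producing subclonal therapy mutations, donor-specific
cycle/dose histories, and real signature profiles. The bundled reference
set is synthetic and near-orthogonal by construction (disjoint
characteristic channel blocks plus a 5% broad floor, deterministic from
the signature name); real COSMIC profiles are more collinear, so
attribution errors on real data will exceed the figures measured here.
Analyses of real cohorts should load genuine reference matrices
(`load_reference_tsv`) and expect the strict-refit detection floor to
matter more.

## Problem sizes, tolerances, degenerate inputs

The test suite and acceptance script run at desk scale by the package's
own choice: B = 1,000 bootstrap iterations (p-resolution 10× finer than
the decision threshold), 100 replicates for coverage/power estimates, 200
simulated donors for type-I error, 2–4 replicate cohorts pooled for
treatment-effect precision. NNLS-oracle agreement is checked on grids of
step 1 (two signatures) and step 5 (three signatures). Degenerate inputs
are handled explicitly rather than left to optimizers: zero-variance or
noise-free burden tables return exact fits with zero variance components
and point CIs; all-zero catalogs return zero exposures with an undefined
(NaN) reconstruction cosine; empty record sets produce correctly shaped
zero matrices. Ties in the strict refit's elimination step break toward
the earlier column; rank-selection ties break toward the smaller rank.

## Known limitations

* The predictive null uses a single clone's residual variance for any
  tested donor, so the excess test is conservative for donors with many
  clones; an exact donor-mean null would need the clone count at null
  construction time.
* The strict refit's detection floor (~9% of catalog at the default
  `max_delta`) censors small exposures; downstream estimates condition on
  detection as described above.
* DBS records are trusted from upstream; no de-duplication against
  overlapping SBS records is attempted.
* The 30% VAF cut is applied identically to all mutation classes,
  including indels and SVs.
* No exposure confidence intervals (signature bootstrapping) and no
  transcriptional-strand-bias (192-channel) contexts.
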