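# Methods

This note documents the models, parameter choices and numerical
conventions behind `metaconcord`, and what the synthetic validation does
and does not establish.

## Synthetic paired cohorts

The generator emulates branched tumor evolution in a patient: a *truncal*
set of alterations acquired before the metastatic lineage diverged (present
in both samples) and *private* alterations on each branch.

**Event model.** Per pair, distinct mutation events are three independent
Poisson draws: truncal (rate *t*), primary-private and metastasis-private
(rates *p₁*, *p₂*). When `trunk_mut_rate` is not given it is derived from
the truncal probability *q* (`trunk_share_prob`) as
*t = q/(1−q)·(p₁+p₂)*, which makes *q* exactly the probability that a
distinct alteration is truncal. Because a truncal event contributes two
shared occurrences and a private event one unshared occurrence, the
expected occurrence-level concordance has the closed form **2q/(1+q)**,
and its estimator 2T/(2T+P) has delta-method standard error
√(4TP(T+P))/(2T+P)², which is what the parameter-recovery tests use as the
95% sampling interval. With *q* = 1 the derivation degenerates, so an
explicit `trunk_mut_rate` is then required (and private rates must be 0).

**Defaults are the study conditions**: 23 pairs; *q* = 0.6 and
*p₁ = p₂ = 2.7* (≈ 22 occurrences per pair, expected concordance 75%);
sequencing depth Poisson with mean 300; cellularity uniform on
[0.5, 1.0]; per-probe Gaussian noise SD 0.15; four copy-number events per
sample in expectation. A mutation event is a catalog driver with
probability 0.08 (the observed recurrent fraction 39/499), otherwise a
random passenger key. Truncal events are fully clonal; private events draw
a clonal fraction uniformly from [0.3, 1.0], so private variants sit at
systematically lower allele fractions — the feature that makes the VAF
cutoff sensitivity analysis informative. Indels are 17% of mutations
(85/499) and differ from SNVs only in allele length.

**Signal models.** A probe's log2 ratio is
`log2((1−c) + c·2^a) + N(0, σ)` with *a* the summed amplitude×clonal
fraction of overlapping events and *c* the cellularity — the linear
tumor/normal mixture a bulk log-ratio measurement actually sees, rather
than the naive attenuation c·a. A variant's expected VAF is
clonal_fraction × cellularity / 2 (heterozygous); depth ~ Poisson(300),
alternate count ~ Binomial(depth, VAF), and calls with zero alternate
reads are not emitted. The toy genome is 4 autosomes × 500 probes (the
production array design of ~161k probes is configuration, not code); sex
chromosomes are never emitted, matching their exclusion from analysis.

**Determinism.** Random streams split per (seed, pair, role) via
`numpy.random.SeedSequence`, so identical config+seed gives byte-identical
files and adding a pair never perturbs earlier pairs.

**What the simulator does not model:** read-level errors and mapping
artifacts, integer copy-number states and subclonal CNA mixtures,
germline contamination, mutational signatures, and realistic genomic
clustering of passenger variants. Passing tests therefore demonstrate the
pipeline's arithmetic and statistical behavior under a clean clonal
model, not robustness to caller- or platform-specific noise.

## Segmentation and CNA calling

Circular binary segmentation, re-implemented as the minimal published
algorithm core: for the current stretch, the arc (i, j) maximizing the
pooled-variance two-sample |t| between interior and exterior is found by
exhaustive search over all arcs (prefix-sum vectorized, O(n²) per
evaluation); the split is accepted when its within-stretch permutation
p-value is below `alpha` (default 0.01, default 1000 permutations, with
early stopping once the exceedance count guarantees rejection), and the
resulting pieces are segmented recursively. Afterwards any segment with
fewer than `min_probes` (default 5) probes is merged into the neighbor
with the closer mean. The pruned/hybrid refinements of the production
implementation are deliberately omitted: at desk scale the exhaustive arc
search *is* the oracle, and breakpoint recovery on noiseless steps is
exact. Zero pooled variance with a nonzero mean difference is treated as
infinite |t| so noiseless steps always win the arc search.

Calling uses strict inequalities at the outer boundaries: mean > 1.0 is
amplification, mean = 1.0 is a gain; 0.5 < mean ≤ 1.0 gain; symmetric for
losses/deletions; |mean| ≤ 0.5 neutral. Coordinates are 1-based inclusive
internally; BED export converts to 0-based half-open.

The GISTIC-like scan scores each probe by the sum over samples of the
smoothed value's excursion beyond the low threshold in the scanned
direction, builds its null by within-sample circular rotation of the
genome-wide smoothed track (preserving each sample's autocorrelation and
alteration load), pools all null probe scores, computes add-one
empirical p-values and Benjamini–Hochberg q-values, and reports maximal
contiguous runs with q < 0.25. Peel-off/arbitrated peel-off peak
deconvolution is out of scope: the scan flags regions, it does not
resolve peaks, and region-level agreement with the production tool is not
claimed. The per-locus group comparison uses two-sided Fisher tests per
probe (gain/amplified and loss/deleted separately); the default
multiplicity control for declaring a locus different is Bonferroni at
0.05 across probes, chosen because the appropriate genome-wide threshold
is otherwise unstated.

## Variant concordance

Variant identity is the genomic key (gene, chrom, pos, ref, alt), not the
protein annotation, whose isoform numbering is unreliable; keys are
assumed left-aligned and minimal by upstream calling. Filters keep calls
with VAF ≥ 0.02 AND depth ≥ 10 AND (no population record OR population
AF ≤ 0.01), boundaries inclusive. Recurrence is catalog count ≥ 10.

Shared-status policy at a VAF cutoff: occurrences below the cutoff leave
both numerator and denominator; under the default **strict** policy the
partner call must itself pass the cutoff to confer shared status, under
**lenient** any detected partner call suffices. Strict is the default
because it is the reading under which a cutoff-sensitivity reanalysis is
self-consistent; the flag allows the comparison. Percents are
round-half-up integers (374/499 → 75, 338/460 → 73).

The class comparison reports the two-sided Fisher exact p together with
*both* odds-ratio estimators — sample cross-product and conditional
maximum likelihood with its exact CI — clearly labeled, because the two
differ and neither is canonically "the" odds ratio of a 2×2 table. On the
packaged fixture's counts ((36,3),(338,122)) the computed two-sided p is
0.0067 with OR ≈ 4.3 by either estimator.

## Similarity and cluster support

Correlation matrices are Pearson r between sample feature vectors —
probe log2 ratios, or VAFs over the union of detected variant keys with
absence encoded as exact 0 (which keeps the correlation well defined and
matches pooling over all detected variants). Zero-variance vectors
produce explicitly-undefined (NaN) entries rather than propagating.
Clustering uses distance 1 − r with Ward linkage.

AU support follows the multiscale-bootstrap construction: features
(probes or variant keys — the observations being resampled) are drawn
with replacement at ratios r = 0.5 … 1.4 (10 scales); per clade the
recovery frequency BP_r is recorded (exact leaf-set identity only);
probit(1 − BP_r) is regressed on (1/√r, √r) by weighted least squares
with binomial weights, giving signed distance v and curvature c, and
AU = 1 − Φ(v − c). BP at r = 1 is the plain bootstrap proportion. Clades
recovered never/always at every scale are degenerate fits and get AU
0/1 with a flag; BP values are clipped to [1/2B, 1 − 1/2B] before the
probit. The tests run 100–1000 replicates per scale; the historical
100-replicates-total setting remains available and simply yields noisier
AU. In bootstrap replicates a resampled sample vector can be constant;
its correlations are set to 0 (distance 1) rather than erroring, since
such replicates are legitimate draws.

## Therapy rules

Rulebooks are data, not code: drug → triggers (gene, alteration class ∈
{amplification, activating_mutation, biallelic_inactivation}). The two
packaged panels carry triggers only where the published selections imply
them — the mTOR arm (everolimus) from PIK3CA/AKT1 activating mutations or
PTEN biallelic inactivation, and the ERBB2 arm (lapatinib ±
trastuzumab) from ERBB2 amplification or activating mutation; the
remaining drugs ship with empty triggers that users must populate from
the trial protocols, because inventing actionability would be worse than
refusing to. Activating mutations come from a hotspot allow-list per
oncogene (the packaged recurrent-variant set), not effect prediction;
ERBB2 L755S is deliberately **not** on the default allow-list because it
is a lapatinib-resistance allele — under the packaged panels it does not
change the selected drug set, which is what makes the packaged
23-patient fixture's single divergent pair the patient whose activating
PIK3CA mutation is primary-only. Biallelic inactivation of a tumor
suppressor requires a deleterious variant plus loss/deletion of the
locus, or a homozygous deletion alone. Selection is monotone (adding an
alteration never removes a drug) and deterministic.

## Clinical summaries and paired tests

Medians use the standard order statistic; categorical percents are
computed over informative records only, with the informative count
reported, and missing values are never imputed. The paired comparison of
per-sample burdens is the Wilcoxon signed-rank test (exact distribution
for n ≤ 25, zeros dropped, two-sided) — the canonical paired analogue of
the Mann-Whitney test, whose unpaired form is exposed alongside. The
packaged clinical fixture transcribes the source table exactly,
including missing grades/statuses and non-contiguous patient ids; its
ERBB2-positive fraction computes to 32% of 19 informative records (the
published summary prints 33%, which is not recoverable from the table as
printed — the computed value is reported, not reconciled, as with the
analogous grade-2–3 percentage).

## Problem sizes

Tests and the acceptance script run the segmentation-heavy stages on
reduced grids — 4 autosomes × 150 probes for cohort-level runs, 100–200
permutations per split test, 500 resamples for the region scan, 10
samples for planted-event recovery — and 10–20 simulated cohorts of 23
pairs for parameter recovery. These sizes were chosen so the whole
validation is a seconds-to-minutes desk computation while every
statistic still operates far from its small-sample edge cases; all
defaults scale to production-sized inputs unchanged.

## Known limitations

Segmentation is O(n²) per split evaluation and intended for array-scale
(10⁴–10⁵ probes per chromosome becomes slow); no allele-specific or
integer copy number; purity is a simulator input, never inferred; the
region scan does not deconvolve peaks; AU support omits later
selective-inference refinements; therapy rules carry no dosing, ranking
or resistance logic beyond what a rulebook encodes.
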