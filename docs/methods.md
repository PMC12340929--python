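# Methods

This note documents the statistical procedures implemented in
`cortexpheno`, the generative models behind its synthetic data, the
numerical choices that were genuinely open, and the limits of what the
test suite demonstrates.

## Random-number discipline

One global seed fans out to named, fixed-key
`numpy.random.SeedSequence` streams (`counts`, `markers`, `calcium`,
`hypnogram`, `tissue`, `module_score`, `permutation`, ...). Adding a
generator never shifts the stream of an existing one, and a fixed seed
yields bit-identical output per generator. Repeated uses of a stream
(per slice, per replicate) are separated by an index in the spawn key.

## Synthetic data: what is emulated, what is not

**Counts.** Sample-level pseudobulk counts follow a negative binomial
with var = µ + µ²·φ (φ → 0 recovers Poisson), per-gene log-normal
relative abundances, uniform library sizes (defaults 0.5–1.5 M), and
N(0, 0.15) per-(gene, batch) log2 offsets. Defaults mirror a
5 HET vs 5 WT design. Planted DE genes multiply the HET mean by
2^(±logFC); planted modules share a per-sample latent factor on the
log2 scale (loading `latent_sd`, default 0.25) and may carry their own
genotype shift. Not emulated: gene–gene correlation outside planted
modules, varying gene length, compositional effects, ambient RNA,
and nucleus-level sampling noise below the sample level — so the suite
validates the statistics' behavior under their own model assumptions,
not robustness to every artifact of real snRNA-seq.

**Marker counts.** Nuclei are assigned a pool and a sex; males draw
Poisson counts (mean 2 per gene) on four Y-linked markers with Xist
fixed at zero, females draw Poisson(8) Xist, and dropout independently
zeroes each count. Real data have correlated capture efficiency and
non-zero opposite-sex background; the dropout parameter is the single
knob standing in for both.

**Calcium.** Each neuron's event train is a per-frame Bernoulli
process (its own rate) plus shared latent-factor events accepted with
a depth-bin-dependent loading; events are convolved with a
single-exponential kernel and placed on a baseline with white noise
and a slowly drifting neuropil component. Because σ in the detection
rules is the SD of the *whole* ΔF/F trace, transients contribute to
their own threshold; the defaults (rate 0.005 Hz, amplitude 4 ΔF/F,
τ = 1.25 s, noise SD 0.03) were derived from the closed-form σ/area
arithmetic so that a transient's peak (≥ 8σ) and summed area (≥ 200σ)
clear the criteria with modest margin while activity stays as sparse
as spontaneous slice recordings. The recorded truth includes the
binary event raster and the exact Pearson correlation of any two
neurons' frame indicators: for X = B ∨ (S_f ∧ T_f) with base rate b,
factor rate q_f, and loading l, independence across factors gives
P(X_i = 0, X_j = 0) = (1−b_i)(1−b_j)·Π_f [1 − q_f(l_i + l_j − l_i l_j)],
from which the covariance and correlation follow. Empirical φ
coefficients on rare binary series are far noisier than the
bivariate-normal formula (1−ρ²)/√T suggests, so all closed-form
comparisons use replicate-based Monte-Carlo standard errors.

**Hypnograms.** A first-order Markov chain over {Wake, NREM, REM} at
10 s epochs, with separate light- and dark-phase transition matrices
switching at ZT12 and the initial state drawn from the light-phase
stationary distribution. Genotype effects are expressed by passing
modified matrices per subject. Bout-duration distributions of real
sleep are only geometric here; the architecture metrics do not depend
on that.

**Tissue.** Soma centers uniform in a box (default 400 × 400 × 200 µm,
N = 10,000), radii normal (6 ± 1 µm, truncated at 0.1). Real cortex
has laminar density gradients; uniformity is what the unbiasedness
claims require and is the appropriate null substrate.

## Differential expression engine

The DE engine is a documented, interchangeable stand-in for the
heavyweight count-model packages a production study would use:
log2(CPM + 1) (pseudocount 1 bounds logFC for zero counts), per-gene
least-squares removal of batch means (re-centered at the grand mean;
equivalent to batch-only regression residuals and neutral for the
Welch *t* in balanced designs), a per-gene Welch two-sample *t*
between genotypes, logFC as the difference of group means of log2
values, BH across tested genes, and baseMean = mean CPM. Genes are
tested if CPM ≥ 1 in at least half the samples of either group — a
proportional version of a fixed-count rule, since per-population
pseudobulk sample counts vary. Zero-variance-in-both-groups genes get
p = 1 by convention. Every downstream stage accepts any externally
produced table with the gene/logFC/pval/padj/baseMean contract, so a
shrinkage-based engine can be plugged in unchanged.

Known limitation: at n = 5 + 5 the *t* approximation on log-counts is
conservative in the far tail (the observed fraction of null p below
10⁻⁴ is ~0.3× nominal in simulation). This propagates to any statistic
gated on "at least one BH discovery" (see burden calibration below).

## Burden and its permutation test

The expression floor θ is the minimum baseMean among genes with raw
p < 0.05 (0 when none). Burden = 100 × significant/expressed above θ,
with adjusted p < 0.05 as the default significance rule (raw-p is
exposed as configuration). The permutation test shuffles sample-level
genotype labels — the sample, not the nucleus, is the experimental
unit — within batch strata when batches exist, and re-runs the full
filter → test → BH → threshold → burden pipeline per shuffle
(re-deriving θ by default; a flag freezes it). With ≤ `n_iter`
distinct assignments the test enumerates all of them and reports the
exact p = #{burden ≥ observed}/#assignments (the identity assignment
is included, so p > 0); otherwise Monte-Carlo with the add-one
estimator (1 + exceedances)/(1 + iterations). A 5 vs 5 design always
takes the exhaustive path (252 assignments).

Calibration: the exact permutation p is valid but conservative for
this statistic, because under the null most relabelings yield zero
burden — rejection requires at least one BH discovery, whose
probability is Simes' α = 0.05 only for exactly uniform gene-level
nulls. With the engine's conservative tail the realized null
rejection rate at α = 0.05 is ≈ 0.02–0.03 in simulation (1,000 null
datasets) rather than 0.05: the test never over-rejects, and its
conservatism is inherited from the stand-in engine's small-sample
tail, not from the permutation machinery.

## Module analysis

`module_score` bins genes into 24 quantile bins of mean expression and
draws 100 control genes per module gene from the gene's bin (excluding
module members), scoring each unit as mean(module) − mean(controls);
the score is invariant to adding a unit-wide constant. `dem_test`
compares a module's member logFC values with the grey genes' by a
Welch two-sample *t* (a one-sample variant against the grey median is
available behind a flag), reports both medians for display, and
Bonferroni-corrects over the number of module × population tests
actually performed in the invocation. Direction is the sign of the
median difference. The "compare medians with a t-test" phrasing in
field usage is interpreted as testing the distributions (a *t*-test
compares means) while displaying medians.

## Demultiplexing and proportions

Sex calls use score_Y = total Y-marker counts and score_X = Xist:
M iff score_Y ≥ 1 and score_X = 0; F iff score_X ≥ 1 and score_Y = 0;
otherwise unknown. The thresholds are explicit package defaults, not
values taken from any published classifier. Genotype is a pure lookup
from (pool, sex) in the pool design; unknown-sex nuclei stay
unassigned. Proportions are modeled untransformed by OLS on
genotype + sex + batch (a logit flag exists for boundary-heavy data),
with two-sided *t* p-values at n − p df and no cross-cell-type
correction by default.

## Calcium processing

The lowpass is a Kaiser-window FIR sized for a 0.5 → 0.65 (of
Nyquist) transition and 25 dB stopband, applied forward-backward
(zero phase, unity DC). F0 defaults to the 20th percentile of the
full corrected trace (rolling-percentile alternative available);
σ is the SD of ΔF/F. Event extent — never standardized in the field's
threshold-crossing descriptions — runs from the onset frame until
ΔF/F first falls below 0.5σ, with overlapping candidates merged; the
area rule is interpreted as Σ ΔF/F over event frames ≥ 200σ
(σ·frames at the native rate). Both are configurable. Correlations on
binary rasters are Pearson (φ); zero-variance rows are excluded
pairwise and counted. The slice mean uses all defined unique bin
pairs including the diagonal; the superficial mean uses matrix rows
whose bin upper edge is ≤ 300 µm (the "neuron-1" definition, with an
either-neuron flag). Slice-level genotype comparisons use the pooled
two-sample *t* with t = 0, p = 1 by convention for identical groups.

## Sleep

Hourly occupancy is computed by exact epoch/hour interval overlap
(the per-second rasterization appears only as a test oracle). Phase
totals sum hours 0–11 and 12–23; SDs are sample (n − 1) SDs of the 12
hourly values — the denominator is a package choice. Genotype
contrasts are Welch *t* with Welch–Satterthwaite df, falling back to
the pooled df with t = 0, p = 1 when both groups are constant. The 12
(state × phase × metric) tests are reported uncorrected.

## Stereology

Sections are z-slabs of thickness t every d µm from a uniform random
start in [0, d); if the region is thinner than d the single section is
placed uniformly inside the region (with a warning) rather than
possibly missing it. Cavalieri uses the exact cross-section area at
each section plane (or a uniformly offset point grid with a/p area per
point). The fractionator's unique counting point is the topmost z of
each soma sphere — a nucleolus surrogate, since the synthetic tissue
does not model nucleoli; a point is counted iff it falls in the
dissector [z+g, z+g+h) of its section and inside a counting frame of a
uniformly offset grid, with half-open frame intervals implementing the
forbidden left/lower exclusion edges. Sampling fractions: ssf = t/d,
asf = frame/grid area, tsf = h/t̄ with t̄ the thickness measured at
counting sites (exactly nominal for synthetic sections; a
number-weighted variant is not needed there). Optional uniform grid
rotation is off by default — unbiasedness on uniform tissue does not
require it. The nucleator draws isotropic unit vectors and returns
(4π/3)·mean(l³); it is exact on spheres for any ray count.
Gundersen-type analytic CE formulas are not implemented; the empirical
CE over random-start replicates is reported instead. The unbiasedness
suite uses a sampling design dense enough for a desk-scale block
(30 × 30 frames on a 60 × 60 grid, d = t = 40 µm, h = 10, g = 2 µm
over 400 × 400 × 200 µm, N = 10,000 — about 625 expected counts per
replicate); the classical cortical field design (18 × 18 frame,
480 × 480 grid, d = 480 µm) samples a ~3 × 10⁻⁵ fraction, which on a
whole cortex yields hundreds of counts but on a desk-scale block would
count fewer than one cell per replicate, so its fraction arithmetic
(ssf = 1/8, asf = 324/230400, tsf = 10/t̄) is verified separately.

## Problem sizes in the test and acceptance runs

Simulation scales are package choices balancing statistical resolution
against desk-scale runtimes: 200 random-start replicates for
estimator unbiasedness (3% tolerance), 200 null datasets for
permutation calibration, 100 simulations for DEM recovery, 1,000
redraws for DEM null uniformity, hour-long (36,000-frame) rasters with
4–6 replicates for correlation closed forms, and 200-replicate power
checks for the proportion and sleep contrasts.
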