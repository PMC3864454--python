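# Methods

This note documents the statistical procedures implemented in `trapcycle`,
the choices made where the design was genuinely open, and the limits of
what the synthetic benchmark can show.

## Experimental design assumed

The pipeline targets a two-day constant-darkness (DD) time course sampled
every 4 h: circadian times CT0, 4, 8, 12, 16, 20 on days 1 and 2 (12
timepoints on the absolute time axis t = 24·(day−1) + CT), with two
biological replicates per sample.  Replicates are pooled by summing raw
reads, so all detection operates on a single 12-point series per gene.
Both detectors test a fixed 24-h period: with 4-h sampling over two cycles
the design cannot genuinely resolve nearby periods, and the biology of
interest is the circadian component.

## Preprocessing

**Pooling** sums raw replicate counts per (CT, day).  Pooling precedes
normalization; the count filter below deliberately uses these raw pooled
values while everything downstream uses normalized values.

**Quantile normalization** maps the value at rank k in each sample to the
across-sample mean of rank-k values.  Ties within a sample receive the mean
of the normalized values over the ranks they occupy — deterministic and
symmetric.  On tie-free data the map is exactly idempotent; with ties a
second application can shift values slightly when tie structures differ
between samples, which is inherent to any rank-mean tie rule and harmless
in practice (the transform is applied once).

## Rank (nonparametric) detector

For each reference phase φ ∈ {0, 4, 8} h the series is scored by Kendall's
S against x = cos(2π(t − φ)/24).  Phases covering only half the period are
scanned because a reference and its antiphase twin give mirror-image S and
identical two-sided p.  Reference values are rounded to 9 decimals so the
exact ties produced by symmetric cosine sampling are treated as ties both
in S and in its null.

The null distribution of S is exact: with distinct series values and
reference tie groups of sizes t₁…t_G, the discordance count is distributed
as the number of inversions of a uniformly random multiset permutation,
whose generating function is the Gaussian q-multinomial
∏ [Σtᵢ choose tᵢ]_q.  The coefficients are accumulated by exact integer
convolution, so p-values carry no sampling or rounding error; the
distribution is cached per tie structure.  Series ties (rare after
normalization) contribute 0 to S while the null conditions only on
reference ties — a documented conservative approximation.  For series
longer than 25 points (not this design) a tie-corrected normal
approximation with continuity correction is substituted.

The minimum per-reference p is Bonferroni-multiplied by the number of
scanned references (3 at the default 4-h step) and capped at 1.  The
detection phase grid equals the sampling interval: finer grids add
multiplicity without adding information at n = 12.  The reported phase is
the winning reference's peak time (its antiphase when S < 0).

Calibration: on 5,000 flat negative-binomial genes (dispersion 0.05) the
rejection rate at the p < 0.015 cutoff is ≈ 0.008–0.010 — conservative, as
expected for a discrete exact test after Bonferroni.

## Harmonic (parametric) detector

Each series is linearly detrended and an AR(6) model (one cycle of
samples) is fitted by both Yule-Walker (MLE variant) and Burg.  The AR
spectral density σ²/|1 − Σ aₖ e^(−2πifk)|² is evaluated on 512 frequencies
in (0, 0.5] cycles/sample; local maxima whose period falls in [20, 28] h
become candidate periods (fallback: 24 h; near-unit-circle AR roots flag
the fit and force the fallback).  Harmonic regression with intercept,
linear trend, and cosine/sine terms is fitted per candidate set, and the
lowest-AIC model supplies the reported period, phase (fitted peak time,
mapped to [0, 24)) and amplitude (√(a² + b²)).  The base 24-h period always
competes as an additional candidate set: the 512-point spectral grid of an
AR(6) fit on 12 points is too coarse to land exactly on 24 h, and without
this set a noiseless 24-h cosine would be assigned a ~22.6-h period with a
~0.8-h phase bias.

**Significance is anchored at 24 h.**  The reported F and p always come
from the fixed 24-h cosinor-with-trend fit (F-test of the two harmonic
terms against the trend-only model, df = (2, 8) at n = 12).  Because those
regressors never depend on the data, the null F distribution is exact; we
measured the rejection rate at α = 0.05 on 5,000 flat NB genes at 0.048.
Computing p from the AIC-selected model instead lets the fitted period
chase noise and inflates the rate to ≈ 0.074.  Anchoring trades a little
power against true non-24-h rhythms — which this design cannot resolve
anyway — for exact type-I control.  The linear trend term absorbs the
slow drift produced by day-2 damping of rhythms in DD.

Across-gene multiplicity uses Benjamini–Hochberg; q-values feed the
expected-false-positive estimate round(q · n_called).

## Filters and calls

A gene is finally called iff (p_rank < 0.015 or p_harmonic < 0.021) and
mean raw pooled count ≥ 20 and relative amplitude ½(max − min)/median ≥ 0.5
on the normalized series.  The p comparisons are strict, the count and
amplitude comparisons inclusive, matching the asymmetry of "less than"
cutoffs versus "at least" filters.  A zero median with a positive swing
gives +∞ amplitude (the gene passes the amplitude filter but rarely the
count filter); an all-zero series gives 0.  The phase of a called gene is
the harmonic fit's phase when that detector called it, else the rank
test's.

## Phase analysis

Day/night classification uses half-open intervals with the boundary at
CT12 (subjective day = [0, 12)).  The bimodality statistic doubles the
phase angles and takes the mean resultant length R of 2θ: R = 1 when all
phases sit at two points 12 h apart, R ≈ 0 for uniform phases.  The two
reported modes are the axial mean direction and its 12-h opposite — by
construction the statistic cannot distinguish a bimodal sample from a
unimodal one (a unimodal von Mises sample still yields two modes 12 h
apart, with smaller R); mixture fitting was deliberately avoided in favour
of a closed-form deterministic statistic.  Histogram bins default to 2 h,
left-closed.

## QC

Replicate agreement is one Pearson r per timepoint across all genes
(expected > 0.9 in a usable experiment; threshold configurable).  The
best-cosine screen correlates each control gene's single-day 6-point
series with all 48 curves cos(2π(t − φ)/24), φ = 0, 0.5, …, 23.5 h, and
takes the maximum r (smallest phase on ties).  A day-dataset passes when
the median best r over the controls reaches `min_best_r` (default 0.8 — a
design choice; the qualitative criterion is "known cyclers should look
like cosines").  Constant control series have undefined r and count as −1
in the median, since a flat known cycler is itself evidence against the
dataset.  The ΔΔCt helper implements relative abundance 2^(−ΔΔCt) against
a reference transcript and baseline timepoint for qPCR-style validation
series.

## Synthetic data

Counts are negative binomial with var = μ + αμ² (α = 0 degenerates to
Poisson), the conventional RNA-seq overdispersion model; the emulated
study states no noise model.  Defaults: 2,000 genes, 10% cyclers,
log₁₀-baseline ~ N(2.0, 0.8), relative amplitudes uniform on [0.3, 1.0],
phases from an equal-weight von Mises mixture at CT6/CT18 with κ = 4
(≈ ±3 h per mode), NB dispersion α = 0.05, library-size factors
log-normal with σ = 0.1, no day-2 damping.  Truth phase is the cosine
peak time, matching both detectors' phase convention.  All draws flow
from one seed through spawned sub-streams (truth, library sizes, counts),
so identical specs give bit-identical matrices.

What the simulation does *not* model: batch effects beyond library size,
transcript-isoform structure, non-sinusoidal waveforms, correlated noise
between genes, and the replicate-asymmetry of a real experiment where one
day's replicate fails QC (the generator supports per-day configurations
but does not default to them).  Passing benchmarks on this generator
therefore demonstrates correctness of the machinery and calibration under
the stated noise model, not performance on any particular real dataset.

## Problem sizes and determinism

The bundled acceptance computation uses 5,000 null genes for calibration,
500 strong cyclers (amplitude ≥ 0.5, baseline ≥ 100 counts) for
sensitivity/phase recovery, and the 2,000-gene default experiment for
structure recovery — sizes at which the binomial error of the reported
rates is a few parts per thousand while the whole computation stays under
a minute.  Every simulation seed derives from the single command-line
seed; rerunning with the same seed reproduces every number exactly.

## Known limitations

* The exact rank null assumes distinct series values; heavy series ties
  make the test more conservative, never liberal.
* The harmonic detector's period estimate is only as fine as AIC selection
  among few spectral candidates; at n = 12 its uncertainty spans several
  hours, and the anchored p-value deliberately does not reward off-24
  period fits.
* Quantile normalization forces identical marginal distributions across
  timepoints; a genome-wide coordinated translation change at one
  timepoint would be normalized away.
* The expected-false-positive count is arithmetic on the BH q-value, not
  an empirical error measurement.
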