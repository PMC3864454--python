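# trapcycle

Circadian rhythm detection in cell-type-specific ribosome-profiling
(TRAP-seq) count time series.

## The problem

Translating Ribosome Affinity Purification (TRAP) captures the mRNAs bound
by tagged ribosomes in a chosen cell population — for example the clock
neurons and glia of the *Drosophila* head — so that sequencing the
immunoprecipitated RNA profiles the cell-type-specific *translatome*.
Sampling such a population every 4 h across two days of constant darkness
(CT0, 4, 8, 12, 16, 20 on DD1 and DD2, two biological replicates) yields,
per gene, a 12-point count series in which circadian translation appears as
a ~24-h oscillation.  `trapcycle` implements the full computational chain
needed to turn the raw gene × sample count matrix into a list of
circadianly translated mRNAs with peak phases:

1. **QC** — per-timepoint Pearson correlation between replicates, and a
   "best cosine correlation" screen that scores known cycling control genes
   against a bank of 48 reference cosines (24-h period, 0.5-h phase steps)
   to flag unusable day-datasets.
2. **Preprocessing** — replicate pooling by read summation, then quantile
   normalization of the pooled 12-timepoint series.
3. **Dual rhythm detection** at a fixed 24-h period:
   * a nonparametric rank test: Kendall's S between the series and
     phase-shifted cosine references, with an **exact** permutation null
     computed by integer dynamic programming (conditioning on reference
     ties), Bonferroni-corrected over the scanned phases;
   * harmonic (cosinor) regression with linear trend, candidate periods
     proposed by autoregressive spectral estimation (Yule-Walker and Burg,
     order 6), model choice by AIC, significance by exact F-test, and
     Benjamini–Hochberg FDR across genes.
4. **Filtering** — mean raw pooled count ≥ 20; relative cycling amplitude
   ½(max − min)/median ≥ 0.5 on the normalized series; detector cutoffs
   p < 0.021 (harmonic) and p < 0.015 (rank), combined as a union with
   full overlap accounting and an expected-false-positive estimate
   round(q · n_called).
5. **Phase analysis** — circular phase histograms, subjective day
   ([CT0, 12)) vs night ([CT12, 24)) classification, per-functional-category
   profiles, phase-ordered heat-map matrices, and an axial (doubled-angle)
   bimodality statistic that quantifies concentration of peak phases at two
   modes 12 h apart (the midday / mid-night pattern).

A ground-truthed simulator of the same experimental design (negative
binomial counts, var = μ + αμ², log-normal library sizes, von Mises phase
mixture, optional day-2 damping) makes every stage testable end to end.

## The model

For gene *g* with baseline *b*, relative amplitude *a* ∈ (0, 1], and peak
phase φ, the expected count in a sample at absolute time *t* with library
factor *s* is

```
μ = s · b · (1 + a · cos(2π(t − φ)/24)),     counts ~ NB(μ, var = μ + αμ²).
```

The harmonic detector fits `y = μ₀ + βt + Σ_k a_k cos(2πt/T_k) + b_k sin(2πt/T_k)`
by OLS and reports amplitude √(a² + b²) and phase as the fitted peak time.
The rank detector computes S = Σ_{i<j} sign(y_j − y_i)·sign(x_j − x_i)
against cosine references x and evaluates P(|S_null| ≥ |S|) exactly over all
permutations of the series.

## Worked example

Simulate the default two-day design (500 genes, 10% cyclers, phases planted
at CT6 and CT18) and run the whole pipeline:

```
$ printf 'simulate:\n  n_genes: 500\n  seed: 42\n' > demo.yaml
$ trapcycle run --simulate --config demo.yaml --seed 42 --outdir demo
called 38 cyclers (rank-only 0, harmonic-only 1, both 37); outputs in demo
```

`demo/cycling_calls.tsv` has one row per gene with every filter quantity:

```
gene_id  mean_raw_count  rel_amplitude  p_rank       p_harmonic  called_by      final_call  phase
g00000   424             0.589157       0.0432323    0.0092024   harmonic       True        21.7419
g00001   608.25          0.386122       0.000952381  0.00730692  harmonic+rank  False       4.91401
```

g00000 passes all three filters and is called with a fitted peak at
CT21.7; g00001 is rhythmic by both detectors but its relative amplitude
(0.39) is below the 0.5 cutoff, so it is excluded.  The phase summary

```
n_day  n_night  bimodality_r  mode_1   mode_2
17     21       0.464309      6.27238  18.2724
```

recovers the planted bimodal structure: 38 called cyclers split almost
evenly between subjective day and night, with axial modes estimated at
CT6.3 and CT18.3 (truth: CT6 and CT18) and axial concentration R = 0.46.
The call summary also reports the expected number of false positives among
the 38 calls (here 3, from the BH q-value 0.088 at the cutoff).

Every stage is also available as a library function
(`trapcycle.pipeline.analyze_counts`, `trapcycle.rank_test`,
`trapcycle.harmonic_test`, …) and as individual subcommands
(`simulate`, `qc`, `preprocess`, `run`).

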