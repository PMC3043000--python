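# circabind

Analysis pipeline for **circadian transcription-factor ChIP-Seq time
courses**: strand-model deconvolution of point binding sites, exact
specific-period rhythmicity testing, tandem E-box sequence modeling with a
weighted HMM, site annotation, and motif-activity inference from expression
time series — exercised end to end on synthetic data with known ground
truth.

## The scientific problem

A circadian transcription factor such as BMAL1/CLOCK binds E-box elements
(CACGTG) rhythmically over the day. ChIP-Seq sampled every 4 h (ZT2–ZT22,
two ChIP libraries plus an input) gives, for every genomic site, a
six-point binding time course and, around every site, sequence that may
carry single E-boxes or tandem E1-E2 elements (canonical CACGTG +
non-canonical AACGTG separated by a short spacer, preferentially 6–7 bp).
The analysis questions are:

1. **Where exactly are the sites?** Sequenced-fragment 5′ ends pile up a
   characteristic offset upstream of the protein-DNA contact on the +
   strand and downstream on the − strand. Deconvolving the two strand
   profiles with this offset kernel localises point sources far more
   precisely than the enclosing enriched region.
2. **Which sites are rhythmic, and when do they peak?** For a series
   x sampled at N equally spaced times over whole days, the periodogram
   fraction at the 24-h harmonic, g = I(24h)/Σ I(f), has an exact null
   distribution under Gaussian noise. For even N (Nyquist ordinate with one
   degree of freedom) the tail is

       P(G > g) = (1 + r)^−(N/2−2) · (1 + 2r)^−1/2,   r = g/(1−g),

   giving exact per-site p-values from only six timepoints. Peak phase is
   the argument of the 24-h Fourier coefficient.
3. **What sequence grammar underlies strong binding?** A segmental HMM with
   background, a GTGT-repeat filter state, an E1 block, an explicit-duration
   spacer (4–20 bp), an E2 block, and a tied reverse-complement mirror is
   trained by Baum–Welch with each site weighted by its tags at peak
   binding; best-path log-odds classify sites as Ø / E1 / E1-E2 and decode
   the spacer.
4. **Does binding drive rhythmic transcription?** Per-timepoint least
   squares of mean-centered expression E_gt on conservation-weighted motif
   site counts N_gm (E_gt = Σ_m N_gm·A_mt + I_t) infers motif activities
   A_mt with standard errors; cycling fractions by binding rank and
   circular phase dispersion by motif class (equality-of-dispersions test)
   summarise the coupling.

All stages are driven by synthetic data whose generator plants the ground
truth (positions, classes, spacers, phases, amplitudes, kernel), so every
claim is checked against known answers.

## Worked example

```python
from circabind.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(outdir="results/demo", seed=1))
sites = bundle["sites"]
print(len(sites), "sites called")
print(sites[["position", "peak_signal", "phase", "p_rhythm", "motif_class"]].head())
```

On the default design (1-Mb genome, 100 planted sites, two ChIP libraries
at 10⁵ tags per library and timepoint) this prints, in under a minute on
one CPU:

```
101 sites called
   position  peak_signal    phase  p_rhythm motif_class
0      3770      25083.0  3.98195  0.010337        E1E2
1     12690      24836.9  7.45081  0.028874        NONE
2     24310      51054.5  7.79807  0.010102        NONE
3     33310      24230.2  4.83784  0.003051          E1
4     43620      33562.8  5.61742  0.015154        NONE
```

`position` is the deconvolved point source (median 3 bp from the planted
center), `peak_signal` the maximal ±250-bp window signal in tags per 10⁷
mapped tags, `phase` the ZT hour of peak binding, `p_rhythm` the exact
specific-period p-value, and `motif_class` the HMM call.

The numbered scripts under `analysis/` run the same stages as a narrated
sequence — `01_simulate.py` … `06_activities.py` — each printing what it
found and writing its tables under `results/analysis/`. On the default
seed the chain recovers 100/100 planted sites (median error 3 bp),
estimates the strand offset at 99.8 bp (simulated: 100 bp), finds 100% of
the top-ranked sites rhythmic with phases concentrated at ZT6.3, detects
the tandem spacing signal at autocorrelation lags 12–13, classifies every
recovered planted tandem site as E1-E2, recovers planted motif activities
with r = 1.000, and finds the tandem-site targets' expression phases
significantly tighter than the rest (equality-of-dispersions p = 0.007).

## Layout

```
src/circabind/      library: synth, tags, discovery, rhythm, motif,
                    annotate, activity, benchmarks, pipeline
analysis/           numbered narrative drivers over the library
scripts/            acceptance.py (benchmark reproduction)
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     model and design notes
```
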