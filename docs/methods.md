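# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the limits of what the synthetic experiments demonstrate.

## Synthetic study design

The generator realises the generative model the analysis inverts, with
defaults fixed to the study conditions:

* **Design.** One synthetic chromosome (default 1 Mb, GC 0.42), 100
  planted sites, six timepoints ZT2–ZT22 at 4-h intervals, two ChIP
  libraries plus one background-only input, 10⁵ tags per library and
  timepoint.
* **Sites.** Classes Ø / E1 / E1-E2 (default 20/45/35); E1 writes CACGTG,
  E1-E2 writes CACGTG + spacer (6 or 7 bp of untouched background) +
  AACGTG. Strengths are log-uniform over 100–1,000 expected tags (one
  order of magnitude, as in strongly bound TF data); phases are
  Normal(ZT6, 1.5 h); relative cosine amplitude 0.8.
* **Tag model.** Each ChIP tag is background (uniform position, random
  strand) or comes from site j with probability proportional to
  strength_j · max(0, 1 + A·cos(2π(t − φ_j)/24)). A site tag falls on
  either strand with probability 1/2 and its 5′ end sits at
  center ∓ offset with offset ~ Normal(µ=100 bp, σ=25 bp) truncated at 0.
  The cosine is clipped at zero so intensities stay valid rates.
* **Background level.** The pipeline default puts ~15% of ChIP tags in
  sites (background weight 0.2 per bp and library). This matters: the
  per-10⁷-tags depth normalisation assumes library totals are dominated by
  background. If sites carry most of the tags, the fixed sequencing depth
  makes normalisation cancel the shared near-ZT6 modulation and genuinely
  rhythmic sites appear flat. Site-dominated libraries are not what real
  TF ChIP looks like (fraction of reads in peaks is typically well under
  30%), so the background-dominated regime is the simulated condition.
* **Expression.** E = N·A + I + noise with Poisson site counts N and
  zero-mean cosine activity rows by default, so E is mean-centered in
  expectation and the regression below is exactly consistent.

What the generator does **not** emulate: chromatin accessibility structure
in the background, sequencing errors, mappability, PCR-duplicate structure
beyond exact-position duplicates, inter-replicate variation in kernel
shape, and correlated biological noise across genes. Tests passing on this
generator therefore certify the statistical machinery (calibration,
localisation, recovery), not robustness to every artefact of real
libraries.

## Tag processing

Duplicates are collapsed per (library, timepoint, chromosome, position,
strand) — one sequencing library is one ChIP sample at one timepoint.
Each library is rescaled to 10⁷ mapped tags and libraries are summed per
timepoint; merging always happens after rescaling. Site signal is the sum
of both strands' weights in the closed window ±250 bp around the site
point, per timepoint. Windows are clipped (not discarded) at chromosome
ends.

## Region detection

A sliding-window (300 bp, half-overlapping) Poisson test of ChIP counts
against the depth-scaled local input rate (max of ±5-kb local and
genome-wide), Benjamini–Hochberg at α = 0.01, fold ≥ 1.4, overlapping
significant windows merged. The fold default is deliberately low: with
~15% of tags in sites, a genuine strength-100 site yields window fold
around 1.6 because the window is mostly background; specificity is carried
by the Poisson/BH test (0–1 false regions per 1-Mb run in practice). The
detector is a stand-in stage — region lists produced elsewhere can be fed
directly to the deconvolution.

## Strand kernel and deconvolution

The offset kernel is estimated from the top-50 regions: the +/− strand
cross-correlation maximum gives the fragment shift (twice the mean
offset); per-region provisional sources (midpoint of strand centroids)
let tag offsets be pooled, histogrammed, smoothed (Gaussian, σ = 5 bp),
floored and symmetrised (the − strand density is the mirror of the +
strand; no strand asymmetry is modeled).

Deconvolution fits non-negative source intensities w_j on a grid (default
step 10 bp) plus a flat per-strand background b by maximising the Poisson
likelihood of both strand profiles under
λ_s(x) = Σ_j w_j·K_s(x − s_j)/2 + b, using multiplicative
Richardson–Lucy-style updates with an optional additive (L1-like) penalty
on the source update. Multiplicative updates guarantee non-negativity and
monotone likelihood ascent; with zero penalty the fit conserves total
signal at convergence (verified to ≤1%). Convergence: relative
log-likelihood change < 10⁻⁸ or 500 iterations (non-convergence at this
strict tolerance is common, harmless — intensities are stable long before
— and is logged and flagged). Sites are local intensity maxima above a
relative floor (5% of the region maximum in the pipeline); maxima closer
than 100 bp merge keeping the stronger, ties to the leftmost. Sites then
pass three filters: minimal peak signal, ±250-bp fold over scaled input
(default 1.4, same rationale as above), and strand balance (each strand
≥ 20% of site tags).

## Rhythmicity statistics

The 24-h Fourier coefficient is c = (2/N)·Σ_t x_t·exp(2πi·t/24); the
amplitude is |c| and the phase (ZT hour of the fitted cosine maximum) is
(24/2π)·arg(c) mod 24. The specific-period test removes the series mean,
forms g = I(24 h)/Σ I over positive frequencies including Nyquist, and
uses the exact null tail for even N derived from the ordinate
distributions (interior: exponential; Nyquist: Gamma(1/2) with twice the
scale) via the Laplace transform of the competing sum:

    P(G > g) = (1 + r)^−(N/2−2) (1 + 2r)^−1/2,  r = g/(1−g);

for odd N this reduces to the classical (1 − g)^((N−1)/2 − 1). The
calibration is certified by Monte-Carlo (20,000 null series: rejection at
0.05 within 3 binomial SE; KS uniformity). Zero-variance series return
p = 1 by convention. No multiple-testing correction is applied to per-site
p-values by default (raw p < 0.05 is the rhythmicity criterion);
Benjamini–Hochberg is available downstream via statsmodels if wanted.

Circular statistics: phases are mapped to angles by 2π/24; the circular
mean is the argument of the mean resultant (undefined at zero resultant).
Equality of polar dispersions across groups uses a Cochran-type
heterogeneity statistic on per-group circular dispersions d_j = 1 − R̄_j
with delta-method variances; its reference distribution is obtained by
label permutation by default (999 permutations; exact under
exchangeability and verified to hold its level), with the asymptotic
χ²(k−1) available as an option. The statistic depends only on deviations
from each group's mean direction, so p is rotation-invariant.

## Tandem E-box model

The fixed scanning matrix assigns the consensus base probability 31/32 per
position with the remaining 1/32 split equally (columns must be proper
distributions). Occupancies are 1/(1 + exp(−slope·ln2·(score − θ))) with θ
the log-odds of the worst single-mismatch word and slope 1 per bit, so
perfect matches exceed 0.5 and two-mismatch words fall below. The spacing
autocorrelation averages per-profile mean-centered ACFs (normalised to 1
at lag 0, start-to-start lags); the pointwise 95% null band permutes
positions within each profile, which preserves marginal occupancy values
while destroying spacing. (Circularly shifting whole profiles does *not*
give a valid null here — a shifted profile retains its internal pair
spacing, so the planted 12–13-bp lag signal would be reproduced in the
"null" band and nothing could ever exceed it.)

The tandem model is a segmental HMM over four segment types emitted from a
background state: a single background base; a short filter block
(initialised to GTGT) absorbing repeat signal; a single E1 block; and a
tandem element E1 + spacer + E2. Blocks have 13 emitting positions — 7
outer flank + 6 core (E1) and 6 core + 7 outer flank (E2) — so a tandem
element with spacer s spans 13 + s + 13 positions while the decoded spacer
equals the core-to-core gap; interior flanks on both sides of each core
would make 6-bp spacers unrepresentable. Spacer durations carry an
explicit learned distribution on 4–20 bp rather than a geometric self-loop
because the biology of interest is an exact 6–7-bp (and ~16–17-bp)
preference that a geometric law blurs. The reverse-complement mirror
shares all parameters and is realised by evaluating each sequence under a
1/2–1/2 orientation mixture, making scores exactly strand-symmetric.
N bases emit probability 1 in every state (no information).

Training is Baum–Welch on the segment grammar with each sequence's
expected counts multiplied by its weight (tags at peak binding); weights
are normalised to mean 1 so uniform weights reduce exactly to unweighted
EM. Initialisation biases the E1/E2 cores to CACGTG/AACGTG at 0.7
(emissions are then learned); pseudocount 10⁻³ per cell; stop when the
weighted log-likelihood gain is below 10⁻⁶ (relative) or after the
configured iterations. The forward recursion is validated against
exhaustive path enumeration on a miniature model.

Classification scores a window in bits of the best path containing a
tandem (respectively single) element over the background-only path,
maximised over orientations. Bit thresholds are recomputed on each
training corpus (smallest score among sequences whose maximum-likelihood
path contains an element of that kind, floored at 2 bits / single + 1
bit); the thresholds learned on real liver data (7.2 / 10.2 bits) are kept
as configuration defaults for untrained use. Spaced matrices for fixed
spacers concatenate E1 block + spacer-many background columns + E2 block
and are scanned as log-odds over both strands; element positions are
reported relative to the deconvolved site center.

## Annotation

Coordinates are 0-based half-open internally; the GTF reader converts at
the boundary. Nearest-TSS assignment is transcript-level, ties broken by
smallest transcript id; distances are signed in transcript orientation
(negative upstream). Categories: promoter (±2 kb of TSS), upstream (−10 to
−2 kb), gene (+2 kb to the polyadenylation site), downstream (polyA to
+10 kb), other. Conservation is the maximum score in ±50 bp (missing
positions score 0). Expressed transcripts are those strictly above the
50th percentile of the provided distribution. Control regions sit 500 bp
downstream (genome + direction — sites are unoriented points) with the
site's window width, flagged when they exceed the chromosome.

## Activity inference

N_gm sums likelihood ratios of the motif matrix along the ±2,500-bp
promoter window (both strands), each weighted by C^0.05 with C the product
of per-base conservation over the motif footprint (footprint, not window:
C multiplies each site's likelihood). The likelihood ratio is
non-negative by construction, so no flooring is needed. Activities solve
an independent ordinary least-squares problem per timepoint (the model is
separable in t) with an intercept; standard errors come from the residual
variance and (XᵀX)⁻¹; rank-deficient designs are rejected with the
offending motifs named. Per-motif cyclic p-values apply the
specific-period test to activity rows. Cycling fraction by rank excludes
unassigned sites from numerator and denominator; "robustly circadian"
defaults to raw p < 0.05.

## Problem sizes

Default experiment sizes were chosen so the whole chain stays interactive
on one CPU: the end-to-end demonstration uses a 1-Mb genome with 100 sites
and 1.2 M ChIP tags (~40 s); the test-null calibration uses 20,000 series;
the localisation benchmark 200 isolated sites; HMM corpora 60–140 windows
of ±50 bp. Scaling any of these up is a configuration change only.

## Known limitations

* The deconvolution assumes a single shared kernel; real fragment-length
  distributions can vary across sites and libraries.
* The exact rhythmicity null assumes i.i.d. Gaussian noise; counting noise
  at very low coverage is over-dispersed relative to this null.
* The tandem model's thresholds recomputed from small corpora are
  permissive (the smallest decoded-hit score), which favours sensitivity;
  on small site sets a few single-box sites gain spurious second boxes.
* The synthetic transcript/expression layers exist to exercise the
  annotation and integration code paths; their effect sizes are
  constructions, not predictions about real livers.
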