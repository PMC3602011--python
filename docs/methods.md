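# Methods

`trillgauge` implements a complete analysis chain for testing whether
physically challenging trill traits signal male quality and predict mating
and reproductive success in a trilling songbird, together with a synthetic
study generator that makes every stage testable against known ground truth.

## Acoustic measurement

Trills are measured from mono PCM waveforms plus selection-table
annotations (tab-delimited; one row per syllable with begin/end times in
seconds and low/high frequencies in Hz; intervals are half-open
`[begin, end)` and times run from recording start).

Two Hann-window STFT presets are used, mirroring standard practice of
selection-based measurement tools:

* **measurement preset** — DFT 4096, hop 111 samples: at 48 kHz this gives
  the 11.72 Hz frequency grid used for bandwidth and pitch;
* **correlation preset** — FFT 1024, 80% overlap (hop 205), used for
  syllable cross-correlation.

The spectrogram convention is explicit: frame *k* covers samples
`[k*hop, k*hop + dft)`; the STFT is computed as one batched FFT over
strided frames.

**99%-energy bandwidth** trims 0.5% of total energy from each tail of the
power spectrum (magnitude squared, pooled over frames), making it
invariant to uniform gain (recording distance).  The returned bandwidth
counts whole bins, so a single occupied bin yields one grid step.  The
analysis window imposes a spectral-smearing floor of roughly 100–150 Hz:
narrow-band fast trills (e.g. 800 Hz bandwidth at 15 syll/s) measure
~10–13% wide, while mid-range trills recover within a few percent.

**Trill rate** is syllable count divided by the first-onset to last-offset
span (a `rate_mode="periods"` switch gives `(n-1)` inter-onset periods
over the onset span instead — the two definitions differ slightly whenever
the final syllable's offset is not one full period after its onset).
**Pitch** is the mean over syllables of the per-syllable 99%-energy high
frequency.  Whole-trill bandwidth is computed on the trill selection's
pooled power spectrum; per-syllable bandwidths are also exposed.  Trill
low/high frequencies (used for correlation bounding) are the min/max of
the per-syllable 99%-energy bounds.

## Performance metrics

**Performance limit.**  Trill rates are partitioned into fixed-width bins
(default 2 syll/s; at least 5 occupied bins required) and ordinary least
squares is run through the maximum-bandwidth trill of each bin.  The
default bin width gives 6–7 occupied bins over typical wren-like rate
ranges (3–16 syll/s).

**Vocal deviation** is the signed orthogonal distance from a trill's
(rate, bandwidth) point to the limit, `D = (aT + b - B) / sqrt(1 + a²)`
with bandwidth in Hz.  Points below the limit are positive (lower D =
closer to the frontier = harder trill); points above the line keep their
negative sign rather than being clipped, preserving information.

**Trill consistency** is the mean of peak normalized spectrogram
cross-correlations over all unordered syllable pairs within a trill.
Before correlating, rows outside `[trill low − 200 Hz, trill high
+ 200 Hz]` are zeroed (background-noise bounding), cells below 50% of each
spectrogram's own peak magnitude are zeroed (an explicit approximation of
the original correlator's broadband masking, whose exact semantics are
unpublished), both matrices are zero-padded to twice their frame count,
and the correlator slides over time lags only — no frequency shifting, so
pitch differences between syllables lower the score.  The score is
`max_lag <A, B_lag> / (||A|| ||B||)`, which is symmetric and lies in
[0, 1] for nonnegative magnitude spectrograms.

For analysis, consistency is variance-stabilised as `-ln(1 - C)` (natural
log; the base is a package convention), with C capped at `1 - 1e-6` so
identical syllables stay finite.

## Paternity

Genotypes are 7-locus microsatellite allele pairs (integer fragment sizes,
0 = missing).  A trio-wise mismatch occurs at a locus when no assignment
of one maternal and one paternal allele explains the offspring's observed
allele set (evaluated by exhaustive enumeration over the ≤4 parental
combinations).  A mismatching locus is *null-consistent* when the
offspring is an apparent homozygote and every parent not carrying its
allele is itself an apparent homozygote — the standard signature of a
non-amplifying (null) allele.

Offspring with more than one non-null trio-wise mismatch are called
extra-pair; zero or one such mismatch keeps them within-pair (single
mismatches with either parent are tolerated as mutations).  Trios with
more than two untyped loci are unresolved.  Candidate extra-pair sires are
all genotyped males present in that year; a candidate qualifies when the
(mother, candidate, offspring) trio is compatible apart from at most one
null-consistent mismatch.  Ties are resolved conservatively: a unique
zero-mismatch candidate wins, otherwise no assignment.

Male-year success pools all social nests within a year (within-pair
proportion), flags simultaneous polygyny (a second nest, different female,
whose active window overlaps the primary's), and counts annual
reproductive success as retained within-pair young plus extra-pair young
sired elsewhere, assuming banded chicks fledge.  Nests flagged for
desertion, ambiguous mate switching, or brood-size manipulation are
excluded via row flags.

Locus summaries report allele counts, observed heterozygosity, and
unbiased expected heterozygosity `(1 - Σ p²) · 2n/(2n - 1)`.

## Statistics

**Mixed models.**  Gaussian responses use a linear mixed model with a
male-identity random intercept, fit by an exact profiled REML: for a fixed
variance ratio λ = σ²_between/σ²_within the GLS solution is closed-form
(group-wise Woodbury), and λ is found by bounded scalar search, with the
boundary λ = 0 checked explicitly.  This is mathematically the same
estimator as a generic mixed-model optimizer but faster by orders of
magnitude across the ~70-model battery and immune to spurious boundary
collapse; it is cross-validated against `statsmodels` `MixedLM` in the
test suite.  Crossed designs (the paired extra-pair/within-pair model)
fall back to `MixedLM` with variance components.

Denominator degrees of freedom use a Satterthwaite approximation computed
from the REML information matrix of (σ²_within, σ²_between):
`df = 2 f² / Var(f)` with `f = c'(X'V⁻¹X)⁻¹c`, the variance by the delta
method.  Within-male covariates get near observation-level df and
male-level covariates near male-level df, as expected.  Crossed models use
a residual-style df (observations − parameters − random levels).

**Binomial responses** (e.g. age class as outcome) use a marginal logistic
model with exchangeable within-male correlation (GEE) and a t reference on
cluster degrees of freedom.  A variational mixed logit was evaluated and
rejected: its understated posterior SDs rejected true nulls at ~0.21
instead of 0.05 at these sample sizes, while the GEE route is calibrated
(≈0.05 measured over 100 null batteries).

**Repeatability** is the covariate-adjusted variance share
σ²_between/(σ²_between+σ²_within) from the REML fit; significance is a
likelihood-ratio test of ML fits with and without the random effect, the
χ²₁ p-value halved because the null variance sits on the parameter-space
boundary (so p = 0.5 exactly at an estimated variance of zero).

**Within/between decomposition** splits a covariate into its mean per
male × trill-type × year combination and the per-trill deviation from that
mean; both enter the model together, separating between-male from
within-male effects.  Mean plus deviation reconstruct the covariate
exactly.

**Effect sizes**: partial r = t/√(t² + df); Cohen's d from pooled (or
paired) SD.  Confidence intervals invert the noncentral-t CDF by bisection
to 1e-8.  **FDR** is Benjamini–Hochberg step-up applied within
table-shaped families (quality-vs-trills; the three mating-success tables
combined; paired comparisons; reproductive success), via
`statsmodels.multipletests` and checked against a brute-force step-up in
the tests.  **VIF** is 1/(1 − R²) per predictor; exact collinearity
reports infinity.

Response transforms follow the field conventions: `sqrt(x + 1)` for
reproductive success, `-ln(1 - C)` for consistency, log for the
heterophile:lymphocyte ratio, `x^0.55` for speaker crossings, and
arcsine-square-root for time near the speaker.  Predictors are left
untransformed.

A caveat the battery inherits from its design: the mating-success models
regress trill measures on a male-year-level predictor with a male random
intercept.  For males observed in several seasons whose success status
changes, the pooled coefficient blends the between-male effect with the
(typically null) within-male contrast, attenuating male-level effects.
The within/between decomposition is the tool that separates these.

## Synthetic data generator

The generator emulates the study conditions, not just convenient test
input.  Defaults: 60 males over seasons 2009–2010 with 14 recorded in
both (≈74 male-years), 40–80 trills per male-year (mean ≈60), extra-pair
rate 0.135, simultaneous polygyny ≈0.21, mean brood 4.5 banded young, and
a 7-locus panel whose allele counts (12, 10, 18, 17, 28, 7, 17) and
null-allele frequencies (0–0.063) mirror a published house-wren-type
marker set.

**Song.**  Each male carries latent Gaussian abilities for deviation and
consistency; trills add within-male noise so the target repeatabilities
(defaults 0.176 and 0.295) equal var_between/(var_between+var_within).
Per-trill deviation D (mean 8.2, SD 3 in orthogonal-distance units) is
converted to bandwidth under the limit `B = -168.5·T + 6019`, clipped so
every trill respects the frontier.  Two cloud shapes are available, since
the true distribution of trills under the limit is not known: the
standalone cloud sampler defaults to exponentially decaying deviations —
the triangular cloud with density approaching the frontier that trill
data show and that upper-bound regression presumes — while the population
simulator uses the Gaussian-latent mode (a constant-width band), whose
linear structure is what the repeatability machinery controls; each mode
is selectable by config flag.  Latent consistency lives on the `-ln(1-C)` scale (mean 1.7,
SD 0.4, i.e. C ≈ 0.64–0.92) where the analysis transform makes the
male-effect structure exactly linear.  Eight syllable types differ in
rate, pitch, and small trait offsets, exercising the acoustic covariates.

**Audio.**  Syllables are linear FM sweeps with Tukey (raised-cosine)
envelopes; the sweep span is scaled by the envelope's own 99%-energy time
fraction so the measured bandwidth matches the target.  Syllable spacing
solves `n / (onset-to-offset span) = rate` exactly.  White Gaussian noise
is added at 30 dB SNR.  Consistency is degraded through one knob: a
multiplicative Gaussian jitter on sweep endpoints and duration, mapped
monotonically from latent consistency (`jitter = 0.12·(1-C)`; at C ≈ 0.82
this yields measured scores near 0.81).  Audio is rendered lazily per
male-year from stored child seeds, so bundles are deterministic without
holding waveforms in memory; rendered consistency is a monotone proxy of
the latent value rather than an exact copy.

**Tabular mode** (the default pipeline path) emits the generator's
measures with small measurement noise (bandwidth SD 30 Hz, consistency SD
0.01) directly, keeping the full statistical battery exercised at a
fraction of the audio cost; the audio path is exercised by its own tests
and the `--audio` pipeline mode (a full-size audio run takes ≈2.5 minutes,
versus ≈45 s tabular).

**Paternity.**  Adult genotypes are drawn from geometric-decay allele
frequencies with locus-specific null alleles (hidden allele id that makes
heterozygotes appear homozygous; two nulls appear as missing).  Offspring
inherit one allele per parent with single-step (±2) mutation at rate
1e-3 per transmission.  Extra-pair sires are drawn from other males
present that year; configurable `effect_sizes` tilt polygyny odds,
per-offspring extra-pair odds, and extra-pair-sire selection weights by
the male's standardized latent trait (the null world, all zeros, is the
default — matching a study whose headline result is a null).

**What the generator does not emulate**: realistic syllable morphology,
reverberation and transmission degradation, annotation error, unsampled
off-site sires, immune-assay biology (indices are pass-through
covariates), and observer effects.  Passing tests therefore demonstrate
correctness of the measurement and inference chain under controlled
conditions, not robustness to every field artifact.

## Validation summary

The test suite checks, among others: the orthogonal-deviation formula
against brute-force nearest-point search (|Δ| < 1e-9); the 99%-band
against an analytic flat spectrum; frontier recovery within ±15%/±10%
on ≥90% of 200 simulated clouds; exact consistency of 1.0 for identical
syllables and strict monotonicity in jitter; exhaustive single-locus trio
truth tables plus zero false extra-pair calls on null-free simulations;
repeatability 0.25 recovered within ±0.05 over 50 seeds; within/between
slopes covered by their 95% CIs in ≥90% of seeds; raw null rejection
0.05 ± 0.02 with FDR-level control over 100 null batteries; the BH
step-up against brute-force enumeration; and bit-identical outputs under
a fixed seed.  Replicate counts and population sizes in these checks
(e.g. 40 males × 15–25 trills for the type-I sweep) are the package's
chosen simulation sizes, giving tight Monte Carlo error at tractable cost.

## Known limitations

* The original correlator's "masking adjustment bias" and "matrix
  standard" semantics are unpublished; the 50%-of-peak masking and
  zero-padding used here are documented approximations, so absolute
  consistency scores are comparable within this package, not across
  tools.
* Kenward–Roger degrees of freedom are approximated by Satterthwaite;
  df values differ in the second decimal range for these designs.
* The deviation scale depends on the fitted limit; with audio-measured
  bandwidths the fitted slope runs ~5–10% steep of truth (spectral
  smearing near the frontier), which shifts D's origin but not the
  rankings the inference uses.
* Assignment of extra-pair sires is rule-based; likelihood-based
  parentage (and null-allele frequency estimation) is out of scope.
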