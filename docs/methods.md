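# Methods

This note documents the models behind each pipeline stage, the
parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the protocol left the
design open.

## Breathing-trace model

The simulator (`synthgen.gen_breath_trace`) represents each breath as a
raised-sine volume pulse: V(t) = A·sin²(π t/d) over a support of
d = min(0.6·IBI, 0.4 s), with amplitude A = V_T / cal_factor in mV.
The recorded flow channel is the *analytic derivative* of this volume
model plus white Gaussian sensor noise, so (i) integrating the flow
recovers the volume waveform up to trapezoid error, and (ii) every
breath's net flow integral is exactly zero before noise — volume is
conserved breath by breath.

Interbreath intervals are Gamma-distributed with mean 60/V_f and
coefficient of variation `ibi_cv`; with probability `p_apnea` an
interval is replaced by an apneic pause drawn Uniform(1.8, 3.0) s. The
lower bound sits strictly above the 1.5 s apnea threshold so planted
apneas are unambiguous to the detector. Amplitudes are jittered
multiplicatively by `amp_cv`. Movement artifacts are 0.5 s broadband
bursts at ten times the pulse amplitude, recorded in the artifact mask.
All randomness flows from a single integer seed; identical parameters
and seed give bitwise-identical traces.

Defaults describe a resting neonatal mouse: V_f = 180 breaths/min
(eupneic; the realized overall rate is lower whenever apneas occur),
V_T = 10 µl, `ibi_cv` = 0.15, `amp_cv` = 0.1, `p_apnea` = 0.05,
sampling at 1 kHz, and flow noise of 1 mV — an amplitude-to-noise
ratio of 10 for the default 10 mV volume pulses. Sampling rate and
noise level are simulator choices, not measured properties of any
instrument; the calibration factor defaults to 1 µl/mV purely as a
round number.

What the simulator does *not* model: gas-exchange physiology, chamber
thermodynamics or temperature/barometric corrections, the shape of
real inspiratory/expiratory asymmetry, baseline wander of real
pressure sensors beyond what integration of noise produces, and the
physiological response to hypoxia/hypercapnia (condition epochs are
labels only). Passing recovery tests therefore demonstrates that the
segmentation and summary arithmetic are correct on well-posed input,
not that the detector is robust to every pathology of real recordings.

## Signal processing

**Integration and drift.** The volume waveform is the cumulative
trapezoidal integral of the flow. Only the integrated waveform is ever
corrected; the pressure trace itself is never filtered or smoothed.
Integration turns any flow offset into baseline drift, so the default
correction subtracts a centered rolling median with a **10 s window**
(reflection-padded at the edges). The window is deliberately long
against both the breath cycle (~0.33 s) and apneic pauses (≤3 s), so
the breath pulses barely deflect the baseline estimate, while
tens-of-seconds drift is still tracked. `none` and `linear` corrections
are available; a noise-free trace needs none.

**Calibration.** The calibration trace (known-volume injections,
20 µl at 3 Hz) is integrated identically; injection peaks are detected
with prominence at half the waveform span, and the factor is
injection volume / mean peak height (µl/mV). At least three detected
pulses are required.

**Breath segmentation** uses hysteresis on the volume waveform: an
excursion starts when the signal rises above `hi_frac` (0.5) of a
running amplitude scale — rolling max−min over 10 s — after having
been below `lo_frac` (0.25); one breath is counted per excursion, with
the earliest sample taken on peak ties and a 100 ms refractory period
between onsets. The reported *onset* is then backtracked from the peak
to the last sample at or below trough + 2% of the breath amplitude.
This convention matters: the hi-threshold crossing of a raised-sine
pulse lags the true pulse start by ~d/4 (50 ms for a 0.2 s breath),
while the 2% backtrack lags by ~d/20, keeping detected onsets within
±25 ms of truth. Onset-to-onset differences define IBIs, so any
residual constant lag cancels in rate, IBI and apnea statistics.

**Analysis windows.** The ventilation rule keeps maximal artifact-free
runs of ≥10 s within the last 300 s of a condition epoch and flags the
selection insufficient below 60 s cumulative. The pattern rule
(apneas, CV, Poincaré) takes artifact-free runs of ≥10 s anywhere in
the epoch, accumulated chronologically up to 600 s. An IBI spanning a
window boundary is excluded from pattern statistics — it mixes time
from different artifact-free stretches.

**Recovery error definition.** Recovered V_f is compared against the
realized ground truth *within the same windows* (true onsets per
window time). The whole-trace mean rate differs from any 300 s window
by a few percent through apnea sampling alone, which is variability of
the truth, not error of the detector; the windowed comparison isolates
detection fidelity. V_T is compared against the realized mean planted
amplitude times the calibration factor.

## Respiratory statistics

Apneas are IBIs strictly greater than 1.5 s (an IBI of exactly 1.5 s
does not qualify). CV defaults to **SE/mean** — the convention used in
these assays — with SD/mean behind `definition="sd"`; sample SD uses
n−1. Group comparisons are unpaired pooled-variance two-sample
t-tests; zero-variance-equal-mean degeneracies yield t = 0, p = 1
rather than NaN. Genotype ratios are tested by χ² goodness of fit with
df = k−1, and expected carrier fractions come from independent
transmission probabilities (homozygous parent 1, hemizygous ½). The
significance convention throughout the respiratory panels is P ≤ 0.05
with no multiple-testing correction, matching standard practice for
these small panels.

## Differential expression

Bead-level robust-spline + VST normalization requires raw array data;
this package's normalization is **quantile normalization of log2
values** (columns share the mean order-statistic vector; within-column
ranks preserved; ties averaged), which preserves the statistical shape
of the analysis at desk scale. Fold changes are 2^(mean log2
difference), signed as 2^l2fc for up and −2^(−l2fc) for down, so the
magnitude is never inside (−1, 1) and the ≥1.2 / ≤−1.2 boundary is
inclusive. FDR adjustment is Benjamini–Hochberg step-up (delegated to
statsmodels; an independent brute-force implementation lives in the
test suite as the oracle).

A caveat worth knowing: with 10% of genes shifted by ±2 log2 units,
quantile normalization compresses the planted effect to roughly ±1.5 —
the usual behaviour when the "most genes unchanged" assumption is
stretched. The power analysis below accounts for this.

### Simulated study design

The expression simulator plants `n_dereg` genes per study shifted by
±`effect_log2` (default 2.0) over N(baseline 8.0, noise 0.5) with an
overlap of `n_overlap` genes between studies, a fraction
`reciprocal_fraction` (default 0.8) of which get opposite signs. The
default **16 samples per group** is a power choice for a validation
harness: after normalization shrinkage the per-gene noncentrality is
≈ 8.5 at df = 30, putting per-gene miss probability below 10⁻⁵ at the
BH-adjusted threshold, so planted-truth recovery checks are sharp
(measured: 0 misses in 8000 planted gene-study events). The all-null
type-I simulations intentionally use the small 3 vs 3 design instead,
since type-I control is exact at any n. Note that BH at FDR 0.05 with
~90% null genes *should* admit roughly 0.045 × (number of calls) false
positives (~8 per study here); observing a handful of false DE calls is
correct behaviour, not a defect.

## Integration

Overlap significance is the one-sided hypergeometric tail
P(X ≥ m | N, n_A, n_B); the reciprocity null is Binomial(m, ½) with an
exact one-sided tail. Both nulls are package choices — the convention
when no test is named — and both are verified against Monte-Carlo
oracles in the tests.

Peak-to-gene assignment re-implements basal-plus-extension regulatory
domains: basal = 5 kb upstream / 1 kb downstream of the TSS
(strand-aware), extended in each direction to the nearest neighbouring
basal domain but no farther than 1 Mb from the TSS. Extended domains
of adjacent genes tile the intergenic gap from both sides, so a
mid-gap peak legitimately associates with both flanking genes; basal
domains are never invaded. Peaks are anchored at their midpoint
(⌊(start+end)/2⌋); signed distance is midpoint − TSS with the sign
flipped on the − strand (negative = upstream), and a distance of
exactly 0 bins as downstream. All coordinates are 0-based half-open.

The peak simulator guarantees non-overlapping basal domains by placing
TSSs with ≥12 kb spacing. For the end-to-end study simulation, target
peaks are planted inside the **basal** domains of genes sampled from
the reciprocal overlap set, making the planted peak→gene truth
unambiguous; decoy peaks go to basal domains of genes deregulated in
neither study (at the default gene density the extended domains tile
the chromosome, so true gene deserts do not exist there — desert
placement remains available for sparse genomes).

## Orchestration

`PipelineConfig` pins the protocol constants (1.5 s apnea threshold,
FDR < 0.05, ±1.2 fold change, 20 µl @ 3 Hz calibration, 10 s/60 s/300 s
ventilation windows, 600 s pattern windows, P ≤ 0.05, GREAT-default
domain sizes) and validates every field; configs load from YAML.
`run_pipeline` records structured errors (insufficient windows, missing
groups) inside the report instead of raising, contains no timestamps,
and is byte-deterministic given config and inputs. All file formats are
plain text (CSV/TSV/BED3/JSON); parse errors name file, line and field.

## Numerical and scale choices

Acceptance-style checks run at desk scale: 600 s traces at 1 kHz
(~1400 breaths), 2000-gene universes with 200 planted effects, 20
all-null replicates, 10 end-to-end seeds, and 10⁵–10⁶-draw Monte-Carlo
oracles; the full suite completes in well under a minute. The
t-vs-permutation agreement is checked against exact enumeration of all
C(11,5) splits and asserted distributionally (median within 0.01;
≥90% within 0.01 where p < 0.05), since the t approximation deviates
from the exact permutation tail at mid-range p-values on such small
samples. The "zero false BH calls per all-null replicate" event has
probability ≈ 0.95 by construction, so replicate counts are asserted
with binomial tolerance rather than as a hard 95%.

## Known limitations

- The breath detector assumes a unimodal volume pulse per breath;
  sighs, double peaks or expiratory braking would need a richer model.
- Quantile normalization is a stand-in for platform-specific
  normalization; absolute fold-change magnitudes are compressed when a
  large fraction of genes move in one direction.
- The reciprocity null of ½ ignores any asymmetry in up/down calling;
  the hypergeometric overlap test conditions on set sizes and assumes
  exchangeable genes.
- Regulatory-domain assignment ignores chromatin context, TADs and
  enhancer maps; it is a distance rule, as in the tools it mirrors.
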