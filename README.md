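# breathomics

Analysis pipeline for transcription-factor **dosage studies in the
developing mouse lung**, built around the kind of experiment that pairs
neonatal respiratory phenotyping with multi-omic target identification:

1. **Head-out pneumotachography** — a pressure (flow) trace from a
   mask-pneumotachograph is integrated into a respiratory volume
   waveform; breaths are segmented and calibrated against known-volume
   injections (20 µl at 3 Hz) to yield respiratory rate
   (V_f, breaths/min), tidal volume (V_T, µl), minute ventilation
   (V_E = V_f · V_T), apnea counts (interbreath interval, IBI, > 1.5 s),
   IBI/amplitude variability (CV, defined here as SE/mean with SD/mean
   available) and Poincaré pairs.
2. **Differential expression** — log2 expression matrices are
   quantile-normalized; each gene gets a pooled-variance two-sample
   t-test; p-values are Benjamini–Hochberg adjusted; deregulated genes
   are called at FDR < 0.05 with signed fold change ≥ 1.2 or ≤ −1.2.
   ΔΔC_T relative quantification (fold = 2^(−ΔΔCt)) covers qPCR
   validation.
3. **Cross-study integration** — deregulated gene sets from a
   gain-of-function and a loss-of-function study are compared by a
   one-sided hypergeometric overlap test; overlap genes are classified
   as concordant or *reciprocal* (opposite directions — the signature of
   a dosage-responsive direct target), with an exact Binomial(m, ½)
   tail for the reciprocal count. ChIP-seq peaks are assigned to genes
   through GREAT-style basal-plus-extension regulatory domains (5 kb
   up / 1 kb down of the TSS, extended to the nearest neighbouring
   basal domain, capped at 1 Mb), and the final triangulation
   intersects ChIP-bound genes with the reciprocally deregulated
   overlap.

No raw data ships with the package: the `synthgen` module simulates
every input — quasi-periodic breathing traces with controllable rate,
volume, variability and apnea probability; paired expression studies
with a planted, partially reciprocal overlap; peaks planted in gene
regulatory domains — and records the exact ground truth, so every
stage is testable end to end.

## Worked example

```python
from breathomics.synthgen import BreathSimParams, gen_breath_trace
from breathomics.pleth import (calibrate, integrate_flow, segment_breaths,
                               select_windows, ventilation_summary)
from breathomics.resp_stats import detect_apneas

trace, cal_trace, truth = gen_breath_trace(BreathSimParams(seed=1))
cal = calibrate(cal_trace)                      # 1.000 ul/mV from 10 injections
series = segment_breaths(integrate_flow(trace))
vwin = select_windows(trace, "room_air", "ventilation")
s = ventilation_summary(series, cal, vwin)
pwin = select_windows(trace, "room_air", "pattern")
ibis = series.ibis_within(pwin)
count, mean_len = detect_apneas(ibis)
```

prints, for this seed:

```
V_f = 140.2 breaths/min   V_T = 9.95 ul   V_E = 1395 ul/min
apneas: 70 of 1398 IBIs (5.0%), mean length 2.29 s
```

The eupneic rate is parameterized at 180 breaths/min and V_T at 10 µl;
the realized overall V_f is lower because 5% of intervals are apneic
pauses of 1.8–3 s, which the detector recovers exactly (the apnea
fraction lands on the planted 5%). The full multi-omic stage runs the
same way:

```python
from breathomics import PipelineConfig, run_pipeline, simulate_study
from breathomics.synthgen import ExprPairSimParams

inputs, truth = simulate_study(ExprPairSimParams(seed=1))
report = run_pipeline(PipelineConfig(seed=1), inputs)
```

For seed 1 the report shows 207 and 210 deregulated genes in the two
studies, an overlap of 101 (hypergeometric p ≈ 7×10⁻⁵³), 81 of the 101
reciprocal (binomial p ≈ 3×10⁻¹⁰), and a triangulated target list that
matches the 10 planted target genes exactly.

A CLI wraps the same stages:

```sh
breathomics --seed 1 simulate --kind breath --out sim/
breathomics pleth --trace sim/trace.csv --cal sim/calibration.csv \
    --mask sim/mask.csv --out summary.json
breathomics --seed 1 report --out report.json
```

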