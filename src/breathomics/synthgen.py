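"""Synthetic input generators with known ground truth.

Every downstream stage of the pipeline is exercised on data produced
here, so each generator records exactly what it planted:

* :func:`gen_breath_trace` — a quasi-periodic neonatal breathing trace
  (pneumotachograph flow in mV) plus a known-volume calibration train
  and the true breath onsets, amplitudes and apnea flags.
* :func:`gen_expression_pair` — two case/control log2 expression studies
  over a shared gene universe with a planted, partially reciprocal,
  overlapping set of deregulated genes.
* :func:`gen_peaks_genes` — ChIP-seq-style peaks planted inside (or
  deliberately outside) GREAT-style gene regulatory domains.

All randomness flows from the single ``seed`` field of each parameter
object; identical parameters and seed give bitwise-identical output.

The breathing model: interbreath intervals are Gamma-distributed with
mean ``60/vf_mean`` and coefficient of variation ``ibi_cv``; with
probability ``p_apnea`` an interval is replaced by an apneic pause drawn
Uniform over ``apnea_ibi_range_s`` (strictly above the 1.5 s apnea
threshold, so ground-truth apneas are unambiguous). Each breath is a
raised-sine (sin²) volume pulse of amplitude ``vt_ul / cal_factor`` mV
jittered by ``amp_cv``, lasting ``min(0.6·IBI, 0.4 s)``; the flow
channel is the analytic time-derivative of the volume model plus
Gaussian sensor noise, so each breath's net flow integral is zero by
construction. Movement artifacts are high-amplitude broadband bursts
recorded in the artifact mask.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pleth import PressureTrace

__all__ = [
    "BreathSimParams",
    "ExprPairSimParams",
    "PeakSimParams",
    "GroundTruth",
    "ExpressionStudy",
    "gen_breath_trace",
    "gen_expression_pair",
    "gen_peaks_genes",
]


class ParameterError(ValueError):
    """Invalid simulation parameters."""


class GenerationError(RuntimeError):
    """Feasible placement could not be found within bounded retries."""


@dataclass
class BreathSimParams:
    """Parameters of the breathing-trace simulator.

    Defaults describe a resting neonatal mouse on room air: 180
    breaths/min, 10 µl tidal volume, moderate cycle-to-cycle
    variability, occasional apneas, and a flow-channel SNR of 10
    (volume-pulse amplitude over noise SD).
    """

    duration_s: float = 600.0
    sampling_rate_hz: float = 1000.0
    vf_mean: float = 180.0  # breaths/min
    vt_ul: float = 10.0  # µl per breath
    ibi_cv: float = 0.15
    amp_cv: float = 0.1
    p_apnea: float = 0.05
    apnea_ibi_range_s: tuple[float, float] = (1.8, 3.0)
    noise_sd: float = 1.0  # mV, on the flow channel
    artifact_rate_per_min: float = 0.0
    cal_factor_ul_per_mv: float = 1.0
    epoch_label: str = "room_air"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.sampling_rate_hz < 100:
            raise ParameterError("sampling_rate_hz must be at least 100 Hz")
        if self.vf_mean <= 0:
            raise ParameterError("vf_mean must be positive")
        if not 0 <= self.p_apnea < 1:
            raise ParameterError("p_apnea must be in [0, 1)")
        if self.apnea_ibi_range_s[0] <= 1.5:
            raise ParameterError("apneic IBIs must be strictly above 1.5 s")
        if self.apnea_ibi_range_s[0] > self.apnea_ibi_range_s[1]:
            raise ParameterError("apnea_ibi_range_s must be (low, high) with low <= high")
        if self.ibi_cv < 0 or self.amp_cv < 0:
            raise ParameterError("ibi_cv and amp_cv must be non-negative")
        if self.vt_ul <= 0 or self.cal_factor_ul_per_mv <= 0:
            raise ParameterError("vt_ul and cal_factor_ul_per_mv must be positive")
        if self.noise_sd < 0 or self.artifact_rate_per_min < 0:
            raise ParameterError("noise_sd and artifact_rate_per_min must be >= 0")


@dataclass
class ExprPairSimParams:
    """Paired gain-/loss-of-function expression study simulator parameters."""

    n_genes_universe: int = 2000
    n_dereg_a: int = 200
    n_dereg_b: int = 200
    n_overlap: int = 100
    reciprocal_fraction: float = 0.8
    effect_log2: float = 2.0
    noise_sd: float = 0.5
    samples_per_group: int = 16
    baseline_log2: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.n_overlap
            <= min(self.n_dereg_a, self.n_dereg_b)
            <= self.n_genes_universe
        ):
            raise ParameterError(
                "need n_overlap <= min(n_dereg_a, n_dereg_b) <= n_genes_universe"
            )
        if self.samples_per_group < 2:
            raise ParameterError("samples_per_group must be at least 2")
        if not 0 <= self.reciprocal_fraction <= 1:
            raise ParameterError("reciprocal_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")


@dataclass
class PeakSimParams:
    """ChIP-seq peak / gene-annotation simulator parameters."""

    genome_length_bp: int = 200_000_000
    n_genes: int = 200
    n_peaks: int = 100
    fraction_in_domains: float = 0.8
    peak_width_bp: int = 500
    placement: str = "domain"  # "domain" (full regulatory domain) or "basal"
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes * 10_000 >= self.genome_length_bp:
            raise ParameterError("genome too short to place genes without basal overlap")
        if not 0 <= self.fraction_in_domains <= 1:
            raise ParameterError("fraction_in_domains must be in [0, 1]")
        if self.placement not in ("domain", "basal"):
            raise ParameterError("placement must be 'domain' or 'basal'")
        if self.n_peaks < 0 or self.peak_width_bp <= 0:
            raise ParameterError("n_peaks must be >= 0 and peak_width_bp positive")


@dataclass
class GroundTruth:
    """What a generator planted, for round-trip testing."""

    breath_onsets_s: np.ndarray | None = None
    breath_amplitudes_mv: np.ndarray | None = None
    apnea_flags: np.ndarray | None = None  # per IBI; length n_breaths - 1
    true_vf: float | None = None  # realized breaths/min
    true_vt: float | None = None  # realized mean µl
    dereg_sets: dict | None = None  # study -> {"up": set, "down": set}
    planted_target_genes: list[str] | None = None

    def to_jsonable(self) -> dict:
        out: dict = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, np.ndarray):
                out[f.name] = v.tolist()
            elif f.name == "dereg_sets":
                out[f.name] = {
                    k: {d: sorted(s) for d, s in v[k].items()} for k in v
                }
            else:
                out[f.name] = v
        return out


@dataclass
class ExpressionStudy:
    """A log2 expression matrix plus case/control labels (synthetic)."""

    values: pd.DataFrame  # genes × samples
    groups: dict[str, str]  # sample id -> "case" | "control"


# ---------------------------------------------------------------------------
# breathing traces
# ---------------------------------------------------------------------------


def _add_raised_sine_flow(
    flow: np.ndarray, fs: float, onset: float, dur: float, amp_mv: float
) -> None:
    """Add the analytic derivative of A·sin²(π(t−onset)/dur) in place."""
    i0 = max(int(np.ceil(onset * fs)), 0)
    i1 = min(int(np.ceil((onset + dur) * fs)), len(flow))
    if i1 <= i0:
        return
    x = np.arange(i0, i1) / fs - onset
    flow[i0:i1] += amp_mv * (np.pi / dur) * np.sin(2 * np.pi * x / dur)


def gen_breath_trace(
    params: BreathSimParams,
) -> tuple[PressureTrace, PressureTrace, GroundTruth]:
    """Simulate a breathing trace plus its calibration train.

    Returns ``(trace, calibration_trace, truth)``. The flow channel is
    the analytic derivative of the raised-sine volume model plus
    Gaussian noise, so integrating it recovers the volume waveform
    exactly up to noise. The calibration trace is a train of ten
    20 µl-equivalent pulses at 3 Hz, noise-free.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate_hz
    n = int(round(params.duration_s * fs))

    mean_ibi = 60.0 / params.vf_mean
    onsets: list[float] = []
    ibis: list[float] = []
    apnea_flags: list[bool] = []
    pos = 0.05 * mean_ibi  # small lead-in before the first breath
    # Stop once a typical pulse no longer fits before the trace end.
    margin = min(0.6 * mean_ibi, 0.4)
    while pos <= params.duration_s - margin:
        onsets.append(pos)
        if rng.random() < params.p_apnea:
            ibi = rng.uniform(*params.apnea_ibi_range_s)
            apnea_flags.append(True)
        else:
            if params.ibi_cv == 0:
                ibi = mean_ibi
            else:
                shape = 1.0 / params.ibi_cv**2
                ibi = rng.gamma(shape, mean_ibi / shape)
            apnea_flags.append(False)
        ibi = max(ibi, 2.0 / fs)
        ibis.append(ibi)
        pos += ibi
    onsets_arr = np.asarray(onsets)
    n_breaths = len(onsets)
    # The draw after the last onset never becomes an IBI.
    apnea_arr = np.asarray(apnea_flags[: max(n_breaths - 1, 0)], dtype=bool)
    ibi_arr = np.asarray(ibis[: max(n_breaths - 1, 0)])

    base_amp_mv = params.vt_ul / params.cal_factor_ul_per_mv
    amps = base_amp_mv * np.maximum(
        rng.normal(1.0, params.amp_cv, size=n_breaths), 0.1
    )

    flow = np.zeros(n)
    for i, onset in enumerate(onsets):
        ibi_next = ibis[i] if i < len(ibis) else mean_ibi
        dur = min(0.6 * ibi_next, 0.4)
        _add_raised_sine_flow(flow, fs, onset, dur, amps[i])
    if params.noise_sd > 0:
        flow += rng.normal(0.0, params.noise_sd, size=n)

    # Movement artifacts: 0.5 s broadband bursts at 10× pulse amplitude.
    mask: list[tuple[float, float]] = []
    n_art = rng.poisson(params.artifact_rate_per_min * params.duration_s / 60.0)
    for _ in range(n_art):
        start = rng.uniform(0.0, max(params.duration_s - 0.5, 0.0))
        end = start + 0.5
        i0, i1 = int(start * fs), int(end * fs)
        flow[i0:i1] += rng.normal(0.0, 10.0 * base_amp_mv, size=i1 - i0)
        mask.append((start, end))
    mask.sort()

    trace = PressureTrace(
        samples=flow,
        sampling_rate_hz=fs,
        epochs=[(params.epoch_label, 0.0, params.duration_s)],
        artifact_mask=mask,
        temperature_c=np.full(n, 36.0),
    )

    # Calibration train: 10 pulses of 20 µl equivalent at 3 Hz, noise-free.
    cal_amp_mv = 20.0 / params.cal_factor_ul_per_mv
    cal_dur_s = 4.0
    nc = int(round(cal_dur_s * fs))
    cal_flow = np.zeros(nc)
    for k in range(10):
        _add_raised_sine_flow(cal_flow, fs, 0.2 + k / 3.0, 0.15, cal_amp_mv)
    cal_trace = PressureTrace(samples=cal_flow, sampling_rate_hz=fs)

    true_vf = 60.0 * n_breaths / params.duration_s
    truth = GroundTruth(
        breath_onsets_s=onsets_arr,
        breath_amplitudes_mv=amps,
        apnea_flags=apnea_arr,
        true_vf=true_vf,
        true_vt=float(np.mean(amps)) * params.cal_factor_ul_per_mv
        if n_breaths
        else None,
    )
    # Sanity invariant for downstream IBI consumers.
    assert len(apnea_arr) == max(n_breaths - 1, 0) and len(ibi_arr) == len(apnea_arr)
    return trace, cal_trace, truth


# ---------------------------------------------------------------------------
# paired expression studies
# ---------------------------------------------------------------------------


def gen_expression_pair(
    params: ExprPairSimParams,
) -> tuple[ExpressionStudy, ExpressionStudy, GroundTruth]:
    """Simulate two case/control studies with a planted overlapping set.

    Study A plays the gain-of-function dataset and study B the
    loss-of-function dataset. ``n_overlap`` genes are deregulated in
    both; ``round(reciprocal_fraction × n_overlap)`` of them carry
    opposite signs between the studies (the dosage-responsive
    signature), the rest the same sign. Non-deregulated genes are pure
    noise around ``baseline_log2``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    genes = np.array([f"g{i:05d}" for i in range(p.n_genes_universe)])
    perm = rng.permutation(p.n_genes_universe)
    overlap_idx = perm[: p.n_overlap]
    only_a = perm[p.n_overlap : p.n_dereg_a]
    only_b = perm[p.n_dereg_a : p.n_dereg_a + (p.n_dereg_b - p.n_overlap)]

    sign_a = np.zeros(p.n_genes_universe)
    sign_b = np.zeros(p.n_genes_universe)
    sign_a[only_a] = rng.choice([-1.0, 1.0], size=len(only_a))
    sign_b[only_b] = rng.choice([-1.0, 1.0], size=len(only_b))
    sign_a[overlap_idx] = rng.choice([-1.0, 1.0], size=len(overlap_idx))
    n_recip = int(round(p.reciprocal_fraction * p.n_overlap))
    recip_idx = overlap_idx[:n_recip]
    concord_idx = overlap_idx[n_recip:]
    sign_b[recip_idx] = -sign_a[recip_idx]
    sign_b[concord_idx] = sign_a[concord_idx]

    def one_study(sign: np.ndarray, tag: str, study_rng: np.random.Generator):
        ns = p.samples_per_group
        cols = [f"{tag}_ctrl{j}" for j in range(ns)] + [
            f"{tag}_case{j}" for j in range(ns)
        ]
        base = p.baseline_log2 + study_rng.normal(
            0.0, p.noise_sd, size=(p.n_genes_universe, 2 * ns)
        )
        base[:, ns:] += (sign * p.effect_log2)[:, None]
        df = pd.DataFrame(base, index=genes, columns=cols)
        groups = {c: ("control" if "ctrl" in c else "case") for c in cols}
        return ExpressionStudy(values=df, groups=groups)

    study_a = one_study(sign_a, "a", rng)
    study_b = one_study(sign_b, "b", rng)

    def sets(sign: np.ndarray) -> dict[str, set[str]]:
        return {
            "up": set(genes[sign > 0]),
            "down": set(genes[sign < 0]),
        }

    truth = GroundTruth(
        dereg_sets={"a": sets(sign_a), "b": sets(sign_b)},
        planted_target_genes=sorted(genes[recip_idx]),
    )
    return study_a, study_b, truth


# ---------------------------------------------------------------------------
# ChIP peaks and gene annotations
# ---------------------------------------------------------------------------


def gen_peaks_genes(
    params: PeakSimParams,
    gene_ids: list[str] | None = None,
    target_gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a peak set (BED-style) and gene TSS annotation table.

    Genes are placed on a single chromosome with enough spacing that
    basal domains never overlap; ``fraction_in_domains`` of the peaks
    are planted inside the regulatory domain of a host gene (the planted
    target), the remainder in gene deserts outside every domain. With
    ``placement="basal"`` hosted peaks stay within the host's basal
    domain, which makes the peak→gene assignment of planted peaks
    unambiguous even between close neighbours.

    ``gene_ids`` overrides the synthetic gene names (e.g. to share a
    universe with an expression simulation); ``target_gene_ids``
    restricts which genes may host planted peaks.

    Returns ``(peaks, gene_annot, truth)`` where ``peaks`` has columns
    ``chrom, start, end`` (0-based half-open) and ``gene_annot`` has
    ``gene_id, chrom, strand, tss_0based``.
    """
    from .integrate import GeneAnnot, regulatory_domains

    p = params
    rng = np.random.default_rng(p.seed)
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(p.n_genes)]
    if len(gene_ids) != p.n_genes:
        raise ParameterError("gene_ids length must equal n_genes")

    # TSS placement with guaranteed >=12 kb spacing (basal span is 6 kb).
    min_gap = 12_000
    slack = p.genome_length_bp - p.n_genes * min_gap
    offsets = np.sort(rng.uniform(0, slack, size=p.n_genes))
    tss = (offsets + min_gap * np.arange(p.n_genes) + min_gap // 2).astype(np.int64)
    strands = rng.choice(["+", "-"], size=p.n_genes)
    gene_annot = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": p.chrom,
            "strand": strands,
            "tss_0based": tss,
        }
    )

    gene_objs = [
        GeneAnnot(gene_id=g, chrom=p.chrom, strand=s, tss=int(x))
        for g, s, x in zip(gene_ids, strands, tss)
    ]
    domains = regulatory_domains(gene_objs, chrom_sizes={p.chrom: p.genome_length_bp})
    dom_by_gene = {d.gene_id: d for d in domains}
    gene_by_id = {g.gene_id: g for g in gene_objs}

    if target_gene_ids is None:
        host_pool = list(gene_ids)
    else:
        missing = set(target_gene_ids) - set(gene_ids)
        if missing:
            raise ParameterError(f"target genes absent from annotation: {sorted(missing)}")
        host_pool = list(target_gene_ids)

    n_in = int(round(p.fraction_in_domains * p.n_peaks))
    half = p.peak_width_bp // 2
    rows: list[tuple[str, int, int]] = []
    planted: list[str] = []
    for _ in range(n_in):
        host = host_pool[int(rng.integers(len(host_pool)))]
        d = dom_by_gene[host]
        g = gene_by_id[host]
        if p.placement == "basal":
            lo, hi = g.basal_domain()
        else:
            lo, hi = d.start, d.end
        mid = int(rng.integers(lo, hi))
        rows.append((p.chrom, max(mid - half, 0), mid + half))
        planted.append(host)

    # Desert peaks: midpoints in the complement of all regulatory domains.
    desert: list[tuple[int, int]] = []
    cursor = 0
    for d in sorted(domains, key=lambda d: d.start):
        if d.start > cursor:
            desert.append((cursor, d.start))
        cursor = max(cursor, d.end)
    if cursor < p.genome_length_bp:
        desert.append((cursor, p.genome_length_bp))
    desert = [(a + half, b - half) for a, b in desert if b - a > p.peak_width_bp + 2]
    n_out = p.n_peaks - n_in
    if n_out > 0 and not desert:
        raise GenerationError("no gene deserts available for out-of-domain peaks")
    lengths = np.array([b - a for a, b in desert], dtype=float)
    for _ in range(n_out):
        k = int(rng.choice(len(desert), p=lengths / lengths.sum()))
        a, b = desert[k]
        mid = int(rng.integers(a, b))
        rows.append((p.chrom, mid - half, mid + half))

    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    truth = GroundTruth(planted_target_genes=sorted(set(planted)))
    return peaks, gene_annot, truth
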