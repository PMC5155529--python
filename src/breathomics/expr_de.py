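"""Differential expression with FDR and fold-change thresholds; ΔΔCt qPCR.

The workflow mirrors a standard two-group bead-array analysis on the
log2 scale: quantile normalization across samples, a per-gene
pooled-variance two-sample t-test, Benjamini–Hochberg FDR adjustment,
and a deregulated-gene call at FDR < 0.05 combined with a signed fold
change of at least ±1.2. The signed fold change is ``2^log2fc`` for
up-regulation and ``−2^(−log2fc)`` for down-regulation, so its
magnitude is never inside (−1, 1).

Relative qPCR quantification uses the ΔΔCt method: fold change =
``2^(−ΔΔCt)`` after normalizing the target gene's Ct to a reference
gene within each condition and then to the control condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pleth import InputError

__all__ = [
    "ExpressionMatrix",
    "DERecord",
    "DeregulatedSets",
    "QpcrMeasurement",
    "normalize_quantile",
    "de_test",
    "bh_fdr",
    "threshold_filter",
    "delta_delta_ct",
    "signed_fold_change",
]


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes × samples) with case/control labels."""

    values: pd.DataFrame
    group_labels: dict[str, str]  # sample id -> "case" | "control"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise InputError("gene ids must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise InputError("expression values must be finite")
        missing = set(self.values.columns) - set(self.group_labels)
        if missing:
            raise InputError(f"samples without group label: {sorted(missing)}")
        for g in ("case", "control"):
            if len(self.samples(g)) < 2:
                raise InputError(f"need at least 2 {g} samples")

    def samples(self, group: str) -> list[str]:
        return [c for c in self.values.columns if self.group_labels[c] == group]


@dataclass
class DERecord:
    gene_id: str
    mean_case: float
    mean_control: float
    log2fc: float
    signed_fc: float
    t_stat: float
    p: float
    fdr: float


@dataclass
class DeregulatedSets:
    """Up/down deregulated gene sets at the thresholds used to call them."""

    up: set[str]
    down: set[str]
    fdr_threshold: float = 0.05
    fc_threshold: float = 1.2

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise InputError("a gene cannot be both up- and down-regulated")

    @property
    def all_genes(self) -> set[str]:
        return self.up | self.down

    @property
    def n_deregulated(self) -> int:
        return len(self.up) + len(self.down)

    def direction_of(self, gene_id: str) -> str:
        if gene_id in self.up:
            return "up"
        if gene_id in self.down:
            return "down"
        raise KeyError(gene_id)

    def percent_up(self) -> float:
        """Up-regulated genes as a percentage of all deregulated genes."""
        if self.n_deregulated == 0:
            raise InputError("no deregulated genes")
        return 100.0 * len(self.up) / self.n_deregulated

    def percent_down(self) -> float:
        """Down-regulated genes as a percentage of all deregulated genes."""
        if self.n_deregulated == 0:
            raise InputError("no deregulated genes")
        return 100.0 * len(self.down) / self.n_deregulated

    @classmethod
    def from_counts(cls, n_up: int, n_down: int, **kw) -> "DeregulatedSets":
        """Build a placeholder set from published counts (ids synthesized)."""
        up = {f"up{i}" for i in range(n_up)}
        down = {f"down{i}" for i in range(n_down)}
        return cls(up=up, down=down, **kw)


@dataclass
class QpcrMeasurement:
    """Ct quartet for one target/reference pair in test vs control."""

    ct_target_test: float
    ct_reference_test: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for f in (
            self.ct_target_test,
            self.ct_reference_test,
            self.ct_target_control,
            self.ct_reference_control,
        ):
            if f <= 0:
                raise InputError("Ct values must be positive")


def signed_fold_change(log2fc: float) -> float:
    """Signed linear fold change: 2^log2fc if ≥0 else −2^(−log2fc)."""
    if log2fc >= 0:
        return float(2.0**log2fc)
    return float(-(2.0**(-log2fc)))


def normalize_quantile(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize the sample columns.

    After normalization every column shares the identical sorted value
    vector — the mean of the per-rank order statistics across samples —
    while within-column ranks are preserved. Ties within a column all
    receive the mean of the reference values at their tied ranks.
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise InputError("quantile normalization needs at least 2 samples")
    arr = df.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    ranks = np.empty(arr.shape[0], dtype=int)
    for j in range(arr.shape[1]):
        ranks[order[:, j]] = np.arange(arr.shape[0])
        col = ref[ranks]
        # Average the reference values over tied input values.
        vals, inv = np.unique(arr[:, j], return_inverse=True)
        if len(vals) < arr.shape[0]:
            sums = np.bincount(inv, weights=col)
            counts = np.bincount(inv)
            col = (sums / counts)[inv]
        out[:, j] = col
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=df.index, columns=df.columns),
        group_labels=dict(matrix.group_labels),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Standard step-up adjustment with monotonicity enforcement; output is
    in [0, 1] and order-equivariant (each adjusted value follows its
    input p regardless of input order).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def de_test(matrix: ExpressionMatrix) -> list[DERecord]:
    """Per-gene pooled-variance two-sample t-test with BH-FDR.

    ``log2fc`` is mean(case) − mean(control) on the log2 scale; the
    linear fold change is recovered as ``2^log2fc`` (the back-transform
    of a log-scale mean difference). Genes with zero variance in both
    groups and equal means are reported as t = 0, p = 1 so the gene
    tally is stable.
    """
    case = matrix.values[matrix.samples("case")].to_numpy(dtype=float)
    ctrl = matrix.values[matrix.samples("control")].to_numpy(dtype=float)
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    res = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    equal = np.isclose(mean_case, mean_ctrl)
    t[degenerate & equal] = 0.0
    p[degenerate & equal] = 1.0
    t[degenerate & ~equal] = np.where(mean_case[degenerate & ~equal] > mean_ctrl[degenerate & ~equal], np.inf, -np.inf)
    p[degenerate & ~equal] = 0.0
    fdr = bh_fdr(p)
    log2fc = mean_case - mean_ctrl
    return [
        DERecord(
            gene_id=str(g),
            mean_case=float(mc),
            mean_control=float(mx),
            log2fc=float(l2),
            signed_fc=signed_fold_change(float(l2)),
            t_stat=float(ti),
            p=float(pi),
            fdr=float(fi),
        )
        for g, mc, mx, l2, ti, pi, fi in zip(
            matrix.values.index, mean_case, mean_ctrl, log2fc, t, p, fdr
        )
    ]


def threshold_filter(
    records: list[DERecord],
    fdr_threshold: float = 0.05,
    fc_threshold: float = 1.2,
) -> DeregulatedSets:
    """Call deregulated genes: FDR < threshold and |signed FC| ≥ threshold.

    The FDR cut is strict (< 0.05) while the fold-change cut includes
    the boundary (≥ 1.2 / ≤ −1.2).
    """
    up = {
        r.gene_id
        for r in records
        if r.fdr < fdr_threshold and r.signed_fc >= fc_threshold
    }
    down = {
        r.gene_id
        for r in records
        if r.fdr < fdr_threshold and r.signed_fc <= -fc_threshold
    }
    return DeregulatedSets(
        up=up, down=down, fdr_threshold=fdr_threshold, fc_threshold=fc_threshold
    )


def delta_delta_ct(m: QpcrMeasurement) -> float:
    """ΔΔCt relative quantification: fold change = 2^(−ΔΔCt)."""
    d_test = m.ct_target_test - m.ct_reference_test
    d_ctrl = m.ct_target_control - m.ct_reference_control
    return float(2.0 ** (-(d_test - d_ctrl)))
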