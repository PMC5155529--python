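"""Respiratory pattern statistics and group-level tests.

Apneas are interbreath intervals (IBIs) strictly longer than 1.5 s.
Breathing variability is summarised as a coefficient of variation
defined, following the source convention for these assays, as standard
error over mean (SE/mean); the conventional SD/mean is available behind
a flag. Group comparisons use the unpaired pooled-variance two-sample
t-test, and genotype ratios from timed matings are tested against
Mendelian expectations with a chi-square goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pleth import InputError, RespiratorySummary

__all__ = [
    "RelativeResponse",
    "GroupComparison",
    "GenotypeCountTable",
    "detect_apneas",
    "variability_cv",
    "poincare_pairs",
    "relative_response",
    "compare_groups",
    "mendelian_chi_square",
    "cross_carrier_fraction",
    "APNEA_THRESHOLD_S",
]

APNEA_THRESHOLD_S = 1.5


@dataclass
class RelativeResponse:
    """Challenge/baseline ratios of the three ventilation quantities."""

    vf_ratio: float
    vt_ratio: float
    ve_ratio: float


@dataclass
class GroupComparison:
    t_stat: float
    df: int
    p_two_sided: float
    mean_a: float
    mean_b: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_two_sided <= 1:
            raise InputError("p-value out of [0, 1]")
        if self.df < 1:
            raise InputError("degrees of freedom must be >= 1")


@dataclass
class GenotypeCountTable:
    """Observed genotype counts with expected Mendelian fractions."""

    categories: list[str]
    observed: list[int]
    expected_fraction: list[float]

    def __post_init__(self) -> None:
        if not (len(self.categories) == len(self.observed) == len(self.expected_fraction)):
            raise InputError("categories, observed and expected_fraction must align")
        if any(o < 0 for o in self.observed):
            raise InputError("observed counts must be non-negative")
        if abs(sum(self.expected_fraction) - 1.0) > 1e-9:
            raise InputError("expected fractions must sum to 1")


def detect_apneas(
    ibis_s, threshold_s: float = APNEA_THRESHOLD_S
) -> tuple[int, float | None]:
    """Count apneic IBIs (strictly longer than ``threshold_s``) and their mean.

    Returns ``(count, mean_length_s)``; the mean is ``None`` when no IBI
    qualifies. The inequality is strict: an IBI of exactly 1.5 s is not
    an apnea.
    """
    ibis = np.asarray(ibis_s, dtype=float)
    if ibis.size == 0:
        raise InputError("empty IBI list")
    apneic = ibis[ibis > threshold_s]
    if apneic.size == 0:
        return 0, None
    return int(apneic.size), float(np.mean(apneic))


def variability_cv(values, definition: str = "se") -> float:
    """Coefficient of variation of IBIs or amplitudes.

    ``definition="se"`` (default) computes SE/mean = (SD/√n)/mean;
    ``definition="sd"`` computes the conventional SD/mean. Sample SD
    uses n−1 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InputError("CV requires at least 2 values")
    mean = float(np.mean(x))
    if mean == 0:
        raise InputError("CV undefined for zero mean")
    sd = float(np.std(x, ddof=1))
    if definition == "se":
        return (sd / np.sqrt(x.size)) / mean
    if definition == "sd":
        return sd / mean
    raise InputError(f"unknown CV definition {definition!r}")


def poincare_pairs(ibis_s) -> list[tuple[float, float]]:
    """Lag-1 pairs (IBI_n, IBI_n+1) for a Poincaré plot."""
    ibis = list(np.asarray(ibis_s, dtype=float))
    return list(zip(ibis[:-1], ibis[1:]))


def relative_response(
    baseline: RespiratorySummary, challenge: RespiratorySummary
) -> RelativeResponse:
    """Challenge-over-baseline ratios for V_f, V_T and V_E.

    The identity V_E = V_f · V_T carries over: the V_E ratio is always
    the product of the other two.
    """
    if baseline.vf <= 0 or baseline.vt <= 0 or baseline.ve <= 0:
        raise InputError("baseline ventilation quantities must be positive")
    return RelativeResponse(
        vf_ratio=challenge.vf / baseline.vf,
        vt_ratio=challenge.vt / baseline.vt,
        ve_ratio=challenge.ve / baseline.ve,
    )


def compare_groups(a, b) -> GroupComparison:
    """Unpaired pooled-variance two-sample t-test (two-sided).

    Degenerate input (zero variance in both groups with equal means)
    yields t = 0, p = 1 rather than NaN so that downstream tallies stay
    stable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    df = int(a.size + b.size - 2)
    res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):  # zero pooled variance
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            t = np.inf if np.mean(a) > np.mean(b) else -np.inf
            p = 0.0
    return GroupComparison(
        t_stat=t,
        df=df,
        p_two_sided=p,
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
    )


def mendelian_chi_square(table: GenotypeCountTable) -> tuple[float, int, float]:
    """Chi-square goodness of fit of genotype counts to expected fractions.

    Returns ``(chi2, df, p)`` with df = k − 1.
    """
    obs = np.asarray(table.observed, dtype=float)
    frac = np.asarray(table.expected_fraction, dtype=float)
    exp = frac * obs.sum()
    if np.any(exp <= 0):
        raise InputError("all expected counts must be positive")
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), len(obs) - 1, float(p)


def cross_carrier_fraction(*transmission_probs: float) -> float:
    """Expected fraction of offspring carrying every listed allele.

    Each argument is the probability that a parent transmits the allele
    of interest: 1 for a homozygous parent, 0.5 for a heterozygous or
    hemizygous one. Independent assortment makes the expected carrier
    fraction the product — e.g. a homozygous knock-in crossed to a
    hemizygous cre driver gives 1 × 0.5 = 0.5 double carriers.
    """
    if not transmission_probs:
        raise InputError("at least one transmission probability required")
    out = 1.0
    for p in transmission_probs:
        if not 0 <= p <= 1:
            raise InputError("transmission probabilities must be in [0, 1]")
        out *= p
    return out
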