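"""Cross-study set statistics and ChIP-seq peak-to-gene triangulation.

Two deregulated gene sets from complementary perturbations (a
gain-of-function and a loss-of-function study) are compared by

* :func:`overlap_test` — one-sided hypergeometric tail probability of
  the observed overlap given the shared gene universe;
* :func:`classify_reciprocity` / :func:`reciprocity_test` — tally of
  concordant vs reciprocal direction pairs among overlap genes, with an
  exact one-sided Binomial(m, ½) tail for the reciprocal count; a gene
  that responds oppositely to gain and loss of a transcription factor
  is the signature of a dosage-responsive direct target;
* :func:`assign_peaks` — GREAT-style basal-plus-extension regulatory
  domains (5 kb upstream / 1 kb downstream of the TSS, extended to the
  nearest neighbouring basal domain, capped at 1 Mb) assigning each
  ChIP peak to every gene whose domain contains its midpoint;
* :func:`three_way_intersect` — the final triangulation: genes bound in
  the ChIP data and deregulated (optionally reciprocally) in both
  expression studies.

All genomic coordinates are 0-based half-open (BED convention); signed
peak–TSS distances are negative upstream of the TSS, with the sign
flipped on the − strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .expr_de import DeregulatedSets
from .pleth import InputError

__all__ = [
    "OverlapResult",
    "ReciprocityResult",
    "Peak",
    "GeneAnnot",
    "RegulatoryDomain",
    "PeakGeneAssoc",
    "overlap_test",
    "classify_reciprocity",
    "reciprocity_test",
    "regulatory_domains",
    "assign_peaks",
    "tss_distance_histogram",
    "three_way_intersect",
]


@dataclass
class OverlapResult:
    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap_genes: set[str]
    p_hypergeometric: float

    @property
    def overlap_size(self) -> int:
        return len(self.overlap_genes)


@dataclass
class ReciprocityResult:
    """Direction-pair tallies over the overlap genes.

    ``uu``/``dd`` are concordant (same direction in both studies),
    ``ud``/``du`` reciprocal (up in one, down in the other).
    """

    uu: int
    dd: int
    ud: int
    du: int
    p_binomial: float | None = None

    @property
    def reciprocal(self) -> int:
        return self.ud + self.du

    @property
    def concordant(self) -> int:
        return self.uu + self.dd

    @property
    def total(self) -> int:
        return self.uu + self.dd + self.ud + self.du


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(f"peak [{self.start}, {self.end}) is malformed")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneAnnot:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 0-based

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise InputError("TSS must be non-negative")

    def basal_domain(self, basal_up: int = 5000, basal_down: int = 1000) -> tuple[int, int]:
        """Strand-aware basal regulatory domain around the TSS."""
        if self.strand == "+":
            return max(self.tss - basal_up, 0), self.tss + basal_down
        return max(self.tss - basal_down, 0), self.tss + basal_up


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class PeakGeneAssoc:
    peak: Peak
    gene_id: str
    signed_distance_bp: int  # negative = upstream of the TSS


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """One-sided hypergeometric test of the overlap of two gene sets.

    With universe size N, |A| = nA and |B| = nB, the overlap m = |A∩B|
    is compared against X ~ Hypergeometric(N, nA, nB):
    p = P(X ≥ m).
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise InputError("both sets must be subsets of the universe")
    m = a & b
    p = float(stats.hypergeom.sf(len(m) - 1, len(universe), len(a), len(b)))
    return OverlapResult(
        universe_size=len(universe),
        set_a_size=len(a),
        set_b_size=len(b),
        overlap_genes=m,
        p_hypergeometric=min(p, 1.0),
    )


def classify_reciprocity(
    overlap_genes: Iterable[str],
    directions_a: dict[str, str],
    directions_b: dict[str, str],
) -> ReciprocityResult:
    """Tally concordant vs reciprocal direction pairs over the overlap.

    Directions are ``"up"``/``"down"`` per study; ``ud`` counts genes up
    in study A and down in study B, ``du`` the converse.
    """
    uu = dd = ud = du = 0
    for g in overlap_genes:
        if g not in directions_a or g not in directions_b:
            raise InputError(f"gene {g!r} lacks a direction in one study")
        da, db = directions_a[g], directions_b[g]
        if da == "up" and db == "up":
            uu += 1
        elif da == "down" and db == "down":
            dd += 1
        elif da == "up" and db == "down":
            ud += 1
        elif da == "down" and db == "up":
            du += 1
        else:
            raise InputError(f"invalid direction pair ({da!r}, {db!r}) for {g!r}")
    return ReciprocityResult(uu=uu, dd=dd, ud=ud, du=du)


def reciprocity_test(reciprocal: int, overlap: int) -> float:
    """Exact one-sided tail P(X ≥ k), X ~ Binomial(m, ½).

    Under the null that each overlap gene is equally likely to respond
    concordantly or reciprocally, the reciprocal count is Binomial(m, ½).
    """
    if not 0 <= reciprocal <= overlap:
        raise InputError("need 0 <= reciprocal <= overlap")
    return float(min(stats.binom.sf(reciprocal - 1, overlap, 0.5), 1.0))


def regulatory_domains(
    genes: Sequence[GeneAnnot],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains for a gene annotation.

    Each gene's basal domain (``basal_up`` upstream, ``basal_down``
    downstream of the TSS, strand-aware) is extended in both directions
    to the nearest neighbouring basal domain, but no farther than
    ``max_ext`` from the TSS. Neighbouring extended domains therefore
    tile the intergenic gap from both sides (a mid-gap position belongs
    to both flanking genes); basal domains are never invaded.
    """
    if len({g.gene_id for g in genes}) != len(genes):
        raise InputError("gene ids must be unique")
    out: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneAnnot]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.tss)
        basals = [g.basal_domain(basal_up, basal_down) for g in gs]
        chrom_end = (chrom_sizes or {}).get(chrom)
        for i, g in enumerate(gs):
            b_start, b_end = basals[i]
            prev_end = basals[i - 1][1] if i > 0 else 0
            next_start = basals[i + 1][0] if i + 1 < len(gs) else None
            start = min(b_start, max(g.tss - max_ext, prev_end))
            if next_start is None:
                cap = g.tss + max_ext
                end = max(b_end, cap if chrom_end is None else min(cap, chrom_end))
            else:
                end = max(b_end, min(g.tss + max_ext, next_start))
            out.append(RegulatoryDomain(g.gene_id, chrom, int(start), int(end)))
    return out


def assign_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnot],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[PeakGeneAssoc]:
    """Assign each peak to every gene whose regulatory domain holds its midpoint.

    The signed distance is midpoint − TSS, with the sign flipped for −
    strand genes so that negative always means upstream of transcription.
    """
    domains = regulatory_domains(genes, basal_up, basal_down, max_ext, chrom_sizes)
    gene_by_id = {g.gene_id: g for g in genes}
    doms_by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        doms_by_chrom.setdefault(d.chrom, []).append(d)
    out: list[PeakGeneAssoc] = []
    for pk in peaks:
        mid = pk.midpoint
        for d in doms_by_chrom.get(pk.chrom, ()):
            if d.start <= mid < d.end:
                g = gene_by_id[d.gene_id]
                dist = mid - g.tss
                if g.strand == "-":
                    dist = -dist
                out.append(PeakGeneAssoc(peak=pk, gene_id=g.gene_id, signed_distance_bp=dist))
    return out


def tss_distance_histogram(
    assocs: Sequence[PeakGeneAssoc],
    bin_edges_kb: Sequence[float] = (0.0, 5.0, 50.0, 500.0, float("inf")),
) -> dict[str, float]:
    """Fraction of associations per signed absolute-distance bin.

    Bins are ``[edge_i, edge_{i+1})`` kb of |distance|, split into
    upstream (negative distance) and downstream (positive or zero —
    a peak exactly at the TSS counts as downstream). Fractions sum to 1.
    """
    if len(assocs) == 0:
        raise InputError("no associations to histogram")
    edges = list(bin_edges_kb)
    labels: list[str] = []
    counts: dict[str, int] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        for side in ("upstream", "downstream"):
            lab = f"{side}_{lo:g}-{hi:g}kb"
            labels.append(lab)
            counts[lab] = 0
    for a in assocs:
        side = "upstream" if a.signed_distance_bp < 0 else "downstream"
        akb = abs(a.signed_distance_bp) / 1000.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            if lo <= akb < hi:
                counts[f"{side}_{lo:g}-{hi:g}kb"] += 1
                break
    n = len(assocs)
    return {lab: counts[lab] / n for lab in labels}


def three_way_intersect(
    chip_genes: Iterable[str],
    dereg_a: DeregulatedSets,
    dereg_b: DeregulatedSets,
    require_reciprocal: bool = True,
) -> list[str]:
    """Genes bound in ChIP and deregulated in both expression studies.

    With ``require_reciprocal`` the directions must be opposite between
    the two studies (up in one, down in the other).
    """
    chip = set(chip_genes)
    if require_reciprocal:
        candidates = (dereg_a.up & dereg_b.down) | (dereg_a.down & dereg_b.up)
    else:
        candidates = dereg_a.all_genes & dereg_b.all_genes
    return sorted(chip & candidates)
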