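"""Overlap/reciprocity statistics and peak-to-gene assignment."""

import numpy as np
import pytest

from breathomics.expr_de import DeregulatedSets
from breathomics.integrate import (
    GeneAnnot,
    Peak,
    assign_peaks,
    classify_reciprocity,
    overlap_test,
    reciprocity_test,
    regulatory_domains,
    three_way_intersect,
    tss_distance_histogram,
)
from breathomics.pleth import InputError


def mc_overlap_tail(N, nA, nB, m_obs, n_draws, seed):
    """Monte-Carlo oracle: random nB-subsets, tail P(|A∩B| >= m_obs)."""
    rng = np.random.default_rng(seed)
    a = np.zeros(N, dtype=bool)
    a[:nA] = True
    count = 0
    for _ in range(n_draws):
        pick = rng.choice(N, size=nB, replace=False)
        if a[pick].sum() >= m_obs:
            count += 1
    return count / n_draws


class TestOverlapTest:
    def test_exact_small_instance(self):
        # N=20, |A|=5, |B|=6, m=4: tail = [C(5,4)C(15,2)+C(5,5)C(15,1)]/C(20,6).
        universe = [f"g{i}" for i in range(20)]
        a = universe[:5]
        b = universe[1:5] + [universe[10], universe[11]]  # overlap = 4
        res = overlap_test(a, b, universe)
        assert res.overlap_size == 4
        assert res.p_hypergeometric == pytest.approx(540 / 38760, rel=1e-9)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(30)]
        res = overlap_test(universe[:5], universe[5:10], universe)
        assert res.overlap_size == 0
        assert res.p_hypergeometric == 1.0

    def test_matches_monte_carlo_oracle(self):
        N, nA, nB = 40, 8, 10
        universe = [f"g{i}" for i in range(N)]
        a = universe[:nA]
        b = universe[4:4 + nB]  # overlap 4
        res = overlap_test(a, b, universe)
        n_draws = 100_000
        p_mc = mc_overlap_tail(N, nA, nB, res.overlap_size, n_draws, seed=0)
        sd = np.sqrt(p_mc * (1 - p_mc) / n_draws)
        assert abs(res.p_hypergeometric - p_mc) <= 3 * sd + 1e-12

    def test_monotone_in_overlap(self):
        universe = [f"g{i}" for i in range(50)]
        ps = []
        for m in range(0, 8):
            a = universe[:10]
            b = universe[10 - m : 20 - m]
            ps.append(overlap_test(a, b, universe).p_hypergeometric)
        assert ps == sorted(ps, reverse=True)

    def test_non_subset_rejected(self):
        with pytest.raises(InputError):
            overlap_test(["x"], ["g0"], ["g0", "g1"])


class TestReciprocity:
    def test_toy_enumeration(self):
        dirs_a = {"g1": "up", "g2": "down", "g3": "up", "g4": "down"}
        dirs_b = {"g1": "down", "g2": "up", "g3": "up", "g4": "up"}
        res = classify_reciprocity(["g1", "g2", "g3", "g4"], dirs_a, dirs_b)
        assert (res.ud, res.du, res.uu, res.dd) == (1, 2, 1, 0)
        assert res.reciprocal == 3
        assert res.concordant + res.reciprocal == res.total == 4

    def test_study_swap_swaps_ud_du(self):
        dirs_a = {"g1": "up", "g2": "down", "g3": "up"}
        dirs_b = {"g1": "down", "g2": "up", "g3": "up"}
        r1 = classify_reciprocity(dirs_a, dirs_a, dirs_b)
        r2 = classify_reciprocity(dirs_a, dirs_b, dirs_a)
        assert (r1.ud, r1.du) == (r2.du, r2.ud)
        assert r1.reciprocal == r2.reciprocal

    def test_missing_direction_rejected(self):
        with pytest.raises(InputError):
            classify_reciprocity(["g1"], {"g1": "up"}, {})

    def test_all_reciprocal_closed_form(self):
        assert reciprocity_test(10, 10) == pytest.approx(2.0**-10)

    def test_zero_reciprocal_p_one(self):
        assert reciprocity_test(0, 25) == 1.0

    def test_matches_simulation(self):
        k, m, n_draws = 15, 20, 1_000_000
        rng = np.random.default_rng(0)
        draws = rng.binomial(m, 0.5, size=n_draws)
        p_mc = float(np.mean(draws >= k))
        sd = np.sqrt(p_mc * (1 - p_mc) / n_draws)
        assert abs(reciprocity_test(k, m) - p_mc) <= 3 * sd

    def test_k_above_m_rejected(self):
        with pytest.raises(InputError):
            reciprocity_test(5, 4)


class TestAssignPeaks:
    def test_basal_domain_assignment_and_distance(self):
        gene = GeneAnnot("g1", "chr1", "+", 100_000)
        assert gene.basal_domain() == (95_000, 101_000)
        peak = Peak("chr1", 96_000, 96_500)  # midpoint 96,250
        assocs = assign_peaks([peak], [gene])
        assert len(assocs) == 1
        assert assocs[0].gene_id == "g1"
        assert assocs[0].signed_distance_bp == -3_750

    def test_distance_sign_flips_on_minus_strand(self):
        gene = GeneAnnot("g1", "chr1", "-", 100_000)
        peak = Peak("chr1", 96_000, 96_500)
        (a,) = assign_peaks([peak], [gene])
        assert a.signed_distance_bp == 3_750  # downstream of a - strand gene

    def test_cap_at_max_extension(self):
        gene = GeneAnnot("g1", "chr1", "+", 100_000)
        far = Peak("chr1", 1_200_000, 1_200_500)  # >1 Mb from the TSS
        assert assign_peaks([far], [gene]) == []

    def test_midgap_peak_assigned_to_both_neighbours(self):
        g1 = GeneAnnot("g1", "chr1", "+", 100_000)
        g2 = GeneAnnot("g2", "chr1", "+", 400_000)
        peak = Peak("chr1", 249_750, 250_250)  # midpoint 250,000
        assocs = assign_peaks([peak], [g1, g2])
        assert {a.gene_id for a in assocs} == {"g1", "g2"}

    def test_domains_respect_neighbour_basal_and_cap(self):
        genes = [
            GeneAnnot(f"g{i}", "chr1", "+", tss)
            for i, tss in enumerate([100_000, 400_000, 5_000_000])
        ]
        doms = {d.gene_id: d for d in regulatory_domains(genes)}
        # g1 extends to g2's basal start, not beyond.
        assert doms["g0"].end == 395_000
        assert doms["g1"].start == 101_000
        # g2 is >1 Mb from g3: capped at max_ext.
        assert doms["g1"].end == 400_000 + 1_000_000
        assert doms["g2"].start == 5_000_000 - 1_000_000

    def test_association_distance_bounded(self):
        rng = np.random.default_rng(5)
        genes = [
            GeneAnnot(f"g{i}", "chr1", rng.choice(["+", "-"]), int(t))
            for i, t in enumerate(np.sort(rng.integers(0, 50_000_000, size=30)))
        ]
        peaks = [
            Peak("chr1", int(s), int(s) + 400)
            for s in rng.integers(0, 50_000_000, size=200)
        ]
        for a in assign_peaks(peaks, genes):
            assert abs(a.signed_distance_bp) <= 1_000_000 + 5_000


class TestDistanceHistogram:
    def test_bin_conventions(self):
        gene = GeneAnnot("g", "chr1", "+", 1_000_000)
        mk = lambda mid: Peak("chr1", mid - 50, mid + 50)
        assocs = assign_peaks(
            [mk(1_000_000), mk(940_000), mk(1_003_000)], [gene]
        )
        h = tss_distance_histogram(assocs)
        assert h["downstream_0-5kb"] == pytest.approx(2 / 3)  # 0 counts as +
        assert h["upstream_50-500kb"] == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        genes = [GeneAnnot("g", "chr1", "+", 2_000_000)]
        peaks = [
            Peak("chr1", int(x), int(x) + 100)
            for x in rng.integers(1_000_000, 3_000_000, size=50)
        ]
        assocs = assign_peaks(peaks, genes)
        assert sum(tss_distance_histogram(assocs).values()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            tss_distance_histogram([])


class TestThreeWay:
    def test_disjoint_inputs_empty(self):
        a = DeregulatedSets(up={"g1"}, down=set())
        b = DeregulatedSets(up=set(), down={"g2"})
        assert three_way_intersect({"g3"}, a, b) == []

    def test_reciprocal_rule(self):
        a = DeregulatedSets(up={"g1"}, down={"g5"})
        b = DeregulatedSets(up={"g5"}, down={"g1", "g2"})
        got = three_way_intersect({"g1", "g2", "g5"}, a, b, require_reciprocal=True)
        assert got == ["g1", "g5"]

    def test_concordant_allowed_when_not_required(self):
        a = DeregulatedSets(up={"g1"}, down=set())
        b = DeregulatedSets(up={"g1"}, down=set())
        assert three_way_intersect({"g1"}, a, b, require_reciprocal=False) == ["g1"]
        assert three_way_intersect({"g1"}, a, b, require_reciprocal=True) == []

    def test_planted_end_to_end_recovery(self):
        from breathomics.config import PipelineConfig
        from breathomics.pipeline import run_pipeline, simulate_study
        from breathomics.synthgen import ExprPairSimParams

        inputs, truth = simulate_study(ExprPairSimParams(seed=17))
        rep = run_pipeline(PipelineConfig(seed=17), inputs)
        assert set(rep["triangulation"]["genes"]) == set(truth.planted_target_genes)
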