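"""Segment merging, score/P-value math and island classification."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import poisson_tail_bruteforce
from toxscan.genome_io import Gene, Genome, Scaffold
from toxscan.island_scan import (
    CandidateSegment,
    ScanParams,
    classify_islands,
    find_candidate_segments,
    genome_density,
    island_score,
    poisson_pvalue,
    scan_genome,
    segment_metrics,
    sweep_gap,
    threshold_curve,
)
from toxscan.synthetic_data import SimParams, make_background_scaffold


def tox_gene(gid, start, end, scaffold="s1", toxin=True, anti=False):
    return Gene(gid, scaffold, start, end, is_toxin=toxin, is_antitoxin=anti)


class TestGenomeDensity:
    def test_single_scaffold(self):
        genes = [tox_gene(f"t{i}", i * 50_000, i * 50_000 + 900) for i in range(40)]
        genome = Genome("g", [Scaffold("s1", 2_000_000, genes)])
        assert genome_density(genome) == pytest.approx(2.0e-5)

    def test_pooled_over_scaffolds(self):
        s1 = Scaffold("s1", 1_000_000,
                      [tox_gene(f"a{i}", i * 90_000, i * 90_000 + 900) for i in range(10)])
        s2 = Scaffold("s2", 1_000_000,
                      [tox_gene(f"b{i}", i * 30_000, i * 30_000 + 900) for i in range(30)])
        assert genome_density(Genome("g", [s1, s2])) == pytest.approx(2.0e-5)

    def test_no_toxinome_genes_gives_zero(self):
        s = Scaffold("s1", 1000, [Gene("A", "s1", 0, 500)])
        assert genome_density(Genome("g", [s])) == 0.0

    def test_zero_length_errors(self):
        with pytest.raises(ValueError, match="zero total length"):
            genome_density(Genome("g", []))


class TestSegmentConstruction:
    def brute_force_runs(self, genes, max_gap):
        """Oracle: split the sorted toxinome gene list at every pairwise
        gap exceeding max_gap."""
        runs, current = [], []
        for g in genes:
            if current and g.start - current[-1].end > max_gap:
                runs.append(current)
                current = []
            current.append(g)
        if current:
            runs.append(current)
        return [(r[0].start, max(g.end for g in r), len(r)) for r in runs]

    def test_matches_pairwise_gap_oracle(self):
        genes = [tox_gene("a", 100, 1100), tox_gene("b", 5100, 6100),
                 tox_gene("c", 40_100, 41_100)]
        scaffold = Scaffold("s1", 100_000, genes)
        segs = find_candidate_segments(scaffold, ScanParams(max_gap_bp=10_000))
        got = [(s.start, s.end, s.T) for s in segs]
        assert got == self.brute_force_runs(genes, 10_000)
        assert got == [(100, 6100, 2), (40_100, 41_100, 1)]

    def test_no_toxinome_genes_gives_no_segments(self):
        scaffold = Scaffold("s1", 10_000, [Gene("A", "s1", 0, 900)])
        assert find_candidate_segments(scaffold, ScanParams()) == []

    def test_gap_exactly_d_is_merged(self):
        genes = [tox_gene("a", 0, 1000), tox_gene("b", 11_000, 12_000)]
        scaffold = Scaffold("s1", 20_000, genes)
        segs = find_candidate_segments(scaffold, ScanParams(max_gap_bp=10_000))
        assert len(segs) == 1
        segs = find_candidate_segments(scaffold, ScanParams(max_gap_bp=9_999))
        assert len(segs) == 2

    def test_every_toxinome_gene_in_exactly_one_segment(self):
        scaffold = make_background_scaffold(
            SimParams(scaffold_length=500_000, toxinome_rate=2e-4, seed=7))
        segs = find_candidate_segments(scaffold, ScanParams())
        member_ids = [gid for s in segs for gid in s.member_genes]
        expected = [g.gene_id for g in scaffold.toxinome_genes]
        assert sorted(member_ids) == sorted(expected)
        assert len(member_ids) == len(set(member_ids))

    def test_metrics_count_overlapping_and_dual_labeled_genes(self):
        genes = [
            tox_gene("a", 100, 1100),
            Gene("u", "s1", 2000, 2500),                     # unlabeled, inside
            tox_gene("b", 5100, 6100, toxin=True, anti=True),  # dual labeled
            Gene("edge", "s1", 6000, 7000),                  # straddles the end
        ]
        scaffold = Scaffold("s1", 10_000, genes)
        (seg,) = find_candidate_segments(scaffold, ScanParams())
        assert (seg.start, seg.end) == (100, 6100)
        assert seg.T == 2
        assert seg.G == 4  # overlap by >= 1 bp counts
        assert (seg.n_toxins, seg.n_antitoxins) == (2, 1)
        assert seg.n_toxins + seg.n_antitoxins >= seg.T


class TestScore:
    @pytest.mark.parametrize(
        "T,G,L,expected",
        [(18, 20, 15_000, 349.92), (4, 8, 8_000, 4.0), (1, 1, 1_000, 1.0)],
    )
    def test_worked_values(self, T, G, L, expected):
        assert island_score(T, G, L) == pytest.approx(expected, rel=1e-9)

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            island_score(4, 0, 1000)
        with pytest.raises(ValueError):
            island_score(0, 1, 1000)

    @settings(derandomize=True, max_examples=200)
    @given(T=st.integers(1, 50), G=st.integers(1, 500), L=st.integers(1, 100_000))
    def test_strict_monotonicity(self, T, G, L):
        s = island_score(T, G, L)
        assert island_score(T + 1, G, L) > s
        assert island_score(T, G + 1, L) < s
        assert island_score(T, G, L + 1) < s


class TestPoisson:
    def test_zero_observations_have_probability_one(self):
        assert poisson_pvalue(0, 0.3) == 1.0
        assert poisson_pvalue(0, 0.0) == 1.0

    @pytest.mark.parametrize(
        "K,lam,expected",
        [(4, 2.0, 0.142877), (18, 0.3, 4.5547e-26)],
    )
    def test_frozen_oracle_values(self, K, lam, expected):
        assert poisson_pvalue(K, lam) == pytest.approx(expected, rel=1e-4)
        assert poisson_pvalue(K, lam) == pytest.approx(
            poisson_tail_bruteforce(K, lam), rel=1e-9)

    def test_tail_dominant_term_bound(self):
        # leading pmf term is a lower bound on and near the tail sum
        lead = math.exp(-0.3) * 0.3**18 / math.factorial(18)
        p = poisson_pvalue(18, 0.3)
        assert lead < p < lead * 1.05

    def test_brute_force_agreement_on_grid(self):
        lams = [0.1 * i for i in range(1, 501, 10)]
        for lam in lams:
            for k in range(0, 101, 5):
                assert abs(poisson_pvalue(k, lam) - poisson_tail_bruteforce(k, lam)) < 1e-12

    @settings(derandomize=True, max_examples=150)
    @given(K=st.integers(0, 80), lam=st.floats(0.01, 50))
    def test_monotone_in_k_and_lambda(self, K, lam):
        p = poisson_pvalue(K, lam)
        assert poisson_pvalue(K + 1, lam) <= p
        assert poisson_pvalue(K, lam * 1.1) >= p

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            poisson_pvalue(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_pvalue(1, -0.5)


class TestClassification:
    def segment(self, T, G, L, n_toxins=None):
        return CandidateSegment(
            genome_id="g", scaffold_id="s1", start=0, end=L,
            member_genes=[f"m{i}" for i in range(T)],
            T=T, n_toxins=T if n_toxins is None else n_toxins,
            n_antitoxins=0, G=G,
        )

    def test_passing_island_composition(self):
        (isl,) = classify_islands([self.segment(18, 26, 15_000)], density=2e-5)
        assert isl.lambda_ == pytest.approx(0.3)
        assert isl.score == pytest.approx(269.2, rel=1e-3)
        assert isl.p_value == pytest.approx(4.5547e-26, rel=1e-3)
        assert isl.passed and isl.fail_reasons == []

    def test_too_few_toxinome_genes(self):
        (isl,) = classify_islands([self.segment(3, 3, 1_000)], density=1e-6)
        assert "count" in isl.fail_reasons and not isl.passed

    def test_low_score_reported(self):
        (isl,) = classify_islands([self.segment(4, 16, 16_000)], density=1e-6)
        assert isl.score == pytest.approx(1.0)
        assert "score" in isl.fail_reasons

    def test_score_boundary_is_strict(self):
        # S exactly 4.0 must fail the "> 4" rule
        (isl,) = classify_islands([self.segment(4, 8, 8_000)], density=1e-6)
        assert isl.score == pytest.approx(4.0)
        assert "score" in isl.fail_reasons

    def test_strict_toxin_count_mode(self):
        seg = self.segment(6, 6, 3_000, n_toxins=2)
        (default,) = classify_islands([seg], density=1e-6)
        assert "count" not in default.fail_reasons
        (strict,) = classify_islands(
            [self.segment(6, 6, 3_000, n_toxins=2)], density=1e-6,
            params=ScanParams(min_toxins_strict=True))
        assert "count" in strict.fail_reasons


class TestScanGenome:
    def test_fixture_yields_single_passing_island(self, thauera_passing):
        (isl,) = thauera_passing
        assert (isl.T, isl.G, isl.L) == (18, 26, 15_000)

    def test_unlabeled_genome_yields_nothing(self):
        s = Scaffold("s1", 10_000, [Gene("A", "s1", 0, 900)])
        assert scan_genome(Genome("g", [s])) == []

    def test_deterministic_across_runs(self, thauera):
        a = scan_genome(thauera)
        b = scan_genome(thauera)
        assert [(i.start, i.end, i.score, i.p_value) for i in a] == \
               [(i.start, i.end, i.score, i.p_value) for i in b]

    def test_merge_refinement_nesting(self):
        # every segment at a smaller D nests inside exactly one at larger D
        for seed in range(50):
            scaffold = make_background_scaffold(
                SimParams(scaffold_length=300_000, toxinome_rate=1e-4, seed=seed))
            genome = Genome(f"g{seed}", [scaffold])
            small = scan_genome(genome, ScanParams(max_gap_bp=5_000))
            large = scan_genome(genome, ScanParams(max_gap_bp=20_000))
            assert len(small) >= len(large)
            for s in small:
                parents = [l for l in large if l.start <= s.start and s.end <= l.end]
                assert len(parents) == 1


class TestSweepAndThresholds:
    def test_single_gap_equals_plain_scan(self, thauera):
        table = sweep_gap(thauera, [10_000])
        islands = scan_genome(thauera)
        assert table.loc[0, "n_segments"] == len(islands)
        assert table.loc[0, "n_passing"] == sum(i.passed for i in islands)

    def test_larger_gap_never_increases_segment_count(self, thauera):
        table = sweep_gap(thauera, [10_000, 20_000, 40_000, 60_000])
        assert list(table["gap"]) == [10_000, 20_000, 40_000, 60_000]
        assert table["n_segments"].is_monotonic_decreasing

    def test_duplicate_gaps_deduplicated(self, thauera):
        table = sweep_gap(thauera, [10_000, 10_000])
        assert len(table) == 1

    def test_threshold_curve_hand_example(self):
        segs = [
            CandidateSegment("g", "s", 0, 100, T=2, G=2, score=5.0, p_value=0.01),
            CandidateSegment("g", "s", 0, 100, T=2, G=2, score=1.0, p_value=0.5),
        ]
        table = threshold_curve(segs, [0.0, 4.0])
        assert list(table["n_surviving"]) == [2, 1]
        assert table.loc[0, "mean_p"] == pytest.approx(0.255)
        assert table.loc[1, "mean_p"] == pytest.approx(0.01)
        assert table.loc[1, "delta_mean_p"] == pytest.approx(0.245)
        assert table.attrs["best_threshold"] == 4.0

    def test_threshold_above_all_scores_is_undefined_mean(self):
        segs = [CandidateSegment("g", "s", 0, 100, T=1, G=1, score=2.0, p_value=0.3)]
        table = threshold_curve(segs, [10.0])
        assert table.loc[0, "n_surviving"] == 0
        assert math.isnan(table.loc[0, "mean_p"])

    def test_unsorted_thresholds_sorted_internally(self):
        segs = [CandidateSegment("g", "s", 0, 100, T=1, G=1, score=2.0, p_value=0.3)]
        table = threshold_curve(segs, [5.0, 0.0])
        assert list(table["threshold"]) == [0.0, 5.0]
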