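import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from subtelo.enrichment import (
    EnrichmentError,
    adjust_bh,
    arm_enrichment,
    bin_enrichment_profile,
    fold_enrichment,
    hypergeom_upper_tail,
    overlap_enrichment,
)
from subtelo.genome import GenomeAssembly, define_subtelomere_windows


def enumerate_tail(k, s, M, N):
    """Exact P(X >= k) by enumerating all C(N, s) draws (oracle)."""
    hits = total = 0
    for combo in itertools.combinations(range(N), s):
        total += 1
        hits += sum(1 for i in combo if i < M) >= k
    return Fraction(hits, total)


class TestHypergeomUpperTail:
    def test_worked_example(self):
        # P(X >= 4) drawing 4 from 10 with 5 successes = C(5,4)C(5,0)/C(10,4)
        assert hypergeom_upper_tail(4, 4, 5, 10) == pytest.approx(5 / 210, abs=1e-15)

    def test_k_zero_is_certain(self):
        assert hypergeom_upper_tail(0, 10, 50, 100) == 1.0

    def test_degenerate_certain_event(self):
        assert hypergeom_upper_tail(7, 7, 7, 7) == 1.0

    @pytest.mark.parametrize("k,s,M,N", [(5, 4, 5, 10), (1, 5, 11, 10), (1, 11, 5, 10)])
    def test_invalid_parameters_error(self, k, s, M, N):
        with pytest.raises(EnrichmentError):
            hypergeom_upper_tail(k, s, M, N)

    def test_matches_enumeration_on_small_populations(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(2, 11))
            s = int(rng.integers(1, N + 1))
            M = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, s + M - N), min(s, M) + 1))
            expected = enumerate_tail(k, s, M, N)
            assert hypergeom_upper_tail(k, s, M, N) == float(expected)

    def test_tail_plus_complement_is_one(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            N = int(rng.integers(2, 400))
            s = int(rng.integers(1, N + 1))
            M = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, s + M - N), min(s, M) + 1))
            upper = hypergeom_upper_tail(k, s, M, N)
            lower = float(stats.hypergeom.cdf(k - 1, N, M, s))
            assert upper + lower == pytest.approx(1.0, abs=1e-10)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_upper_tail_is_a_decreasing_probability_in_k(data):
    """P(X >= k) lies in (0, 1] and decreases as k grows."""
    N = data.draw(st.integers(1, 300))
    s = data.draw(st.integers(0, N))
    M = data.draw(st.integers(0, N))
    k = data.draw(st.integers(max(0, s + M - N), min(s, M)))
    p = hypergeom_upper_tail(k, s, M, N)
    assert 0 < p <= 1
    if k + 1 <= min(s, M):
        assert hypergeom_upper_tail(k + 1, s, M, N) <= p


class TestFoldEnrichment:
    def test_ratio_of_proportions(self):
        assert fold_enrichment(10, 100, 50, 1000) == pytest.approx(2.0)

    def test_null_expectation_is_one(self):
        assert fold_enrichment(5, 50, 100, 1000) == pytest.approx(1.0)

    def test_zero_k_gives_zero(self):
        assert fold_enrichment(0, 50, 100, 1000) == 0.0

    def test_empty_interval_gives_nan(self):
        assert np.isnan(fold_enrichment(0, 50, 0, 1000))

    def test_scale_invariance_in_sample(self):
        for c in (2, 3, 10):
            assert fold_enrichment(3 * c, 30 * c, 40, 500) == pytest.approx(
                fold_enrichment(3, 30, 40, 500)
            )


def make_distances(n_genes, bin0_genes, deg_bin0, deg_total, bin_width=1000):
    """Distance table with deg_bin0 of deg_total DEGs in the first bin."""
    ids = [f"g{i}" for i in range(n_genes)]
    dist = np.full(n_genes, bin_width + 10)
    dist[:bin0_genes] = 5
    degs = ids[:deg_bin0] + ids[bin0_genes:bin0_genes + (deg_total - deg_bin0)]
    frame = pd.DataFrame(
        {"gene_id": ids, "chrom": "chr1", "arm": "chr1p",
         "distance_bp": dist, "anchor": "nearest_edge"}
    )
    return frame, degs


class TestBinProfile:
    def test_all_degs_in_first_bin(self):
        distances, degs = make_distances(1000, 100, 10, 10)
        profile = bin_enrichment_profile(degs, distances, bin_width=1000,
                                         max_distance=3000)
        row = profile.iloc[0]
        assert (row.k, row.s, row.M, row.N) == (10, 10, 100, 1000)
        assert row.fold_enrichment == pytest.approx(10.0)

    def test_proportional_degs_give_unit_fe(self):
        # 10% of genes in bin 0 and 10% of DEGs in bin 0 -> FE = 1 in both bins
        distances, degs = make_distances(1000, 100, 10, 100)
        profile = bin_enrichment_profile(degs, distances, bin_width=1000,
                                         max_distance=2000)
        assert profile["fold_enrichment"].dropna().tolist() == pytest.approx([1.0, 1.0])

    def test_bin_sums_partition_the_genome(self, default_genome, default_config):
        from subtelo.genome import distance_table
        from subtelo.simulate import generate_deg_set

        assembly, genes = default_genome
        distances = distance_table(genes, assembly)
        deg_set, _ = generate_deg_set(assembly, genes, default_config,
                                      distances=distances)
        max_d = 15_000_000
        profile = bin_enrichment_profile(sorted(deg_set.up), distances,
                                         bin_width=2_000_000, max_distance=max_d)
        near = distances["distance_bp"] < max_d
        assert profile["M"].sum() == int(near.sum())
        assert profile["k"].sum() == int(
            (near & distances["gene_id"].isin(deg_set.up)).sum()
        )

    def test_deg_missing_from_table_errors(self):
        distances, _ = make_distances(100, 10, 0, 0)
        with pytest.raises(EnrichmentError, match="missing"):
            bin_enrichment_profile(["nope"], distances, 1000, 2000)


class TestArmEnrichment:
    @pytest.fixture
    def four_chrom_setup(self):
        chroms = tuple((f"c{i}", 10_000_000) for i in range(4))
        asm = GenomeAssembly(chroms, {f"c{i}": (5_000_000, 5_000_000) for i in range(4)})
        windows = define_subtelomere_windows(asm, 2_000_000)
        rows = []
        gid = 0
        for i in range(4):
            for d in np.linspace(0, 4_900_000, 50).astype(int):
                rows.append((f"g{gid}", f"c{i}", f"c{i}p", d, "nearest_edge"))
                gid += 1
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "arm", "distance_bp", "anchor"]
        ), windows

    def test_single_loaded_arm_is_flagged(self, four_chrom_setup):
        distances, windows = four_chrom_setup
        degs = distances.loc[
            (distances["arm"] == "c0p") & (distances["distance_bp"] < 2_000_000),
            "gene_id",
        ]
        frame = arm_enrichment(degs, distances, windows)
        by_arm = frame.set_index("label")
        assert bool(by_arm.loc["c0p", "flagged"])
        others = by_arm.drop("c0p")["fold_enrichment"].dropna()
        assert (others <= 1.0).all()

    def test_no_degs_gives_unit_p(self, four_chrom_setup):
        distances, windows = four_chrom_setup
        frame = arm_enrichment([], distances, windows)
        assert (frame["p_value"] == 1.0).all()
        assert not frame["flagged"].any()

    def test_gene_desert_window_not_flagged(self, four_chrom_setup):
        distances, windows = four_chrom_setup
        # q arms have no genes at distance < 2 Mb in this construction
        frame = arm_enrichment(["g0"], distances, windows).set_index("label")
        assert np.isnan(frame.loc["c0q", "fold_enrichment"])
        assert not frame.loc["c0q", "flagged"]


class TestOverlapEnrichment:
    def test_subset_of_universe_sized_b(self):
        a = set(range(10))
        b = set(range(100))
        assert overlap_enrichment(a, b, 100).fold_enrichment == pytest.approx(1.0)

    def test_disjoint_sets(self):
        res = overlap_enrichment(set(range(3)), set(range(10, 13)), 1000)
        assert res.fold_enrichment == 0.0
        assert res.p_value == 1.0

    def test_worked_example_against_brute_force(self):
        a = set(range(6))
        b = set(range(3, 13))          # |A ∩ B| = 3, |B| = 10
        res = overlap_enrichment(a, b, 100)
        assert res.fold_enrichment == pytest.approx(5.0)
        expected = sum(
            stats.hypergeom.pmf(i, 100, 10, 6) for i in range(3, 7)
        )
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_universe_smaller_than_union_errors(self):
        with pytest.raises(EnrichmentError, match="universe"):
            overlap_enrichment(set(range(5)), set(range(5, 10)), 8)


class TestAdjustBH:
    def test_step_up_arithmetic(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        adj = adjust_bh(p)
        assert (adj <= 1).all() and (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
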