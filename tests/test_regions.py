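"""Region chaining, direction of effect, lead pairing and the reshuffle null."""

import numpy as np
import pytest

from conftest import make_table
from crosscoloc import (
    direction_of_effect,
    distinct_regions,
    harmonize,
    pair_by_lead_distance,
    reshuffle_empirical_p,
    shared_regions,
)
from crosscoloc.regions import Region, count_close_pairs, territory_from_positions
from crosscoloc.simulate import BlockSpec, CausalAssignment, ScenarioSpec, simulate_pair


def _paired(pos, p_a, p_b, beta_a=0.1, beta_b=0.1):
    n = len(pos)
    ids = [f"rs{k}" for k in range(n)]
    kw = {}
    a = make_table("a", variant_id=ids, pos=pos, pvalue=list(p_a),
                   beta=beta_a if np.ndim(beta_a) else [beta_a] * n)
    b = make_table("b", variant_id=ids, pos=pos, pvalue=list(p_b),
                   beta=beta_b if np.ndim(beta_b) else [beta_b] * n)
    return harmonize(a, b)


def _region(chrom, lead_pos, lead_id="lead", start=None, end=None, trait="a"):
    start = lead_pos - 50_000 if start is None else start
    end = lead_pos + 50_000 if end is None else end
    return Region(chrom, start, end, [lead_id], lead_id, lead_pos, 1e-8, trait)


class TestSharedRegions:
    def test_chain_of_ten_spans_450kb(self):
        pos = [1 + 50_000 * k for k in range(10)]
        paired = _paired(pos, [1e-4] * 10, [1e-4] * 10)
        regions = shared_regions(paired)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (1, 450_001)
        assert r.n_snps == 10

    def test_nine_snps_insufficient(self):
        pos = [1 + 1000 * k for k in range(9)]
        paired = _paired(pos, [1e-4] * 9, [1e-4] * 9)
        assert shared_regions(paired) == []

    def test_requires_both_traits_low(self):
        pos = [1 + 1000 * k for k in range(12)]
        paired = _paired(pos, [1e-4] * 12, [0.5] * 12)
        assert shared_regions(paired) == []

    def test_planted_shared_causal_recovered(self):
        hits = 0
        for s in range(100):
            sc = ScenarioSpec(
                blocks=[BlockSpec(40, 0.95)],
                causal_assignments=[CausalAssignment(0, 20, 8, 8)],
                n_samples_ref=50,
                seed=80_000 + s,
            )
            a, b, _, _ = simulate_pair(sc)
            paired = harmonize(a, b)
            causal_pos = 1 + 20 * 5000
            regions = [r for r in shared_regions(paired)
                       if r.start_bp <= causal_pos <= r.end_bp]
            hits += len(regions) == 1
        assert hits >= 90


class TestDistinctRegions:
    def test_no_significant_snps(self):
        table = make_table(variant_id=["rs0", "rs1"], pos=[1, 2], pvalue=0.5)
        assert distinct_regions(table) == []

    def test_single_cluster_lead_is_min_p(self):
        pos = [1 + 1000 * k for k in range(12)]
        pvals = [1e-7] * 12
        pvals[4] = 1e-9
        table = make_table(variant_id=[f"rs{k}" for k in range(12)], pos=pos, pvalue=pvals)
        regions = distinct_regions(table)
        assert len(regions) == 1
        assert regions[0].lead_id == "rs4"

    def test_two_clusters_split_at_large_gap(self):
        pos = [1 + 1000 * k for k in range(12)] + [160_000 + 1000 * k for k in range(12)]
        table = make_table(
            variant_id=[f"rs{k}" for k in range(24)], pos=pos, pvalue=1e-7
        )
        regions = distinct_regions(table)
        # brute-force chaining oracle: split wherever adjacent gap >= 100 kb
        gaps = np.diff(pos)
        assert (gaps >= 100_000).sum() == 1
        assert len(regions) == 2

    def test_chained_region_may_span_beyond_gap(self):
        # adjacent gaps below 100 kb chain into one region spanning ~400 kb
        pos = [1 + 40_000 * k for k in range(11)]
        table = make_table(variant_id=[f"rs{k}" for k in range(11)], pos=pos, pvalue=1e-7)
        regions = distinct_regions(table)
        assert len(regions) == 1
        assert regions[0].size_bp == 400_000


class TestDirection:
    def test_all_opposite(self):
        pos = [1 + 1000 * k for k in range(10)]
        paired = _paired(pos, [1e-4] * 10, [1e-4] * 10, beta_a=0.2, beta_b=-0.3)
        region = shared_regions(paired)[0]
        assert direction_of_effect(region, paired) == "opposite"

    def test_all_same(self):
        pos = [1 + 1000 * k for k in range(10)]
        paired = _paired(pos, [1e-4] * 10, [1e-4] * 10, beta_a=0.2, beta_b=0.3)
        region = shared_regions(paired)[0]
        assert direction_of_effect(region, paired) == "same"

    def test_mixed(self):
        pos = [1 + 1000 * k for k in range(10)]
        beta_b = [0.3] * 5 + [-0.3] * 5
        paired = _paired(pos, [1e-4] * 10, [1e-4] * 10, beta_a=0.2, beta_b=beta_b)
        region = shared_regions(paired)[0]
        assert direction_of_effect(region, paired) == "mixed"

    def test_zero_beta_members_excluded(self):
        pos = [1 + 1000 * k for k in range(10)]
        beta_b = [0.3] * 9 + [0.0]
        paired = _paired(pos, [1e-4] * 10, [1e-4] * 10, beta_a=0.2, beta_b=beta_b)
        region = shared_regions(paired)[0]
        assert direction_of_effect(region, paired) == "same"


class TestPairing:
    def test_printed_lead_positions(self):
        # worked examples: lead-SNP distances at two loci reported as
        # 247,460 bp and 249,018 bp
        nb = [_region("3", 158_211_291, "rs1978779"), _region("4", 4_892_294, "rs11944652")]
        chd = [_region("3", 158_458_751, "rs75107964"), _region("4", 4_643_276, "rs4689909")]
        pairs = pair_by_lead_distance(nb, chd)
        dist = {p.region_a.lead_id: p.lead_distance_bp for p in pairs}
        assert dist == {"rs1978779": 247_460, "rs11944652": 249_018}

    def test_identical_leads_distance_zero(self):
        pairs = pair_by_lead_distance([_region("1", 500_000)], [_region("1", 500_000)])
        assert pairs[0].lead_distance_bp == 0

    def test_threshold_is_strict(self):
        pairs = pair_by_lead_distance([_region("1", 0)], [_region("1", 250_000)])
        assert pairs == []

    def test_different_chromosomes_never_pair(self):
        pairs = pair_by_lead_distance([_region("1", 100)], [_region("2", 100)])
        assert pairs == []

    def test_symmetric_under_trait_swap(self):
        ra = [_region("1", 100_000), _region("1", 900_000), _region("2", 5_000)]
        rb = [_region("1", 150_000), _region("2", 240_000)]
        ab = {(p.region_a.lead_pos, p.region_b.lead_pos)
              for p in pair_by_lead_distance(ra, rb)}
        ba = {(p.region_b.lead_pos, p.region_a.lead_pos)
              for p in pair_by_lead_distance(rb, ra)}
        assert ab == ba

    def test_planted_distinct_pair_not_shared(self):
        pair_hits = 0
        for s in range(100):
            sc = ScenarioSpec(
                blocks=[BlockSpec(100, 0.95)],
                causal_assignments=[
                    CausalAssignment(0, 25, 8, 0),
                    CausalAssignment(0, 70, 0, 8),  # 225 kb away
                ],
                n_samples_ref=50,
                seed=50_000 + s,
            )
            a, b, _, _ = simulate_pair(sc)
            paired = harmonize(a, b)
            pairs = pair_by_lead_distance(distinct_regions(a), distinct_regions(b))
            pair_hits += bool(pairs) and not shared_regions(paired)
        assert pair_hits >= 85


class TestReshuffle:
    TERR = {"1": (1, 10_000_000), "2": (1, 10_000_000)}

    def test_zero_observed_pairs_gives_one(self):
        ra = [_region("1", 1_000_000)]
        rb = [_region("2", 1_000_000)]
        assert reshuffle_empirical_p(ra, rb, self.TERR, n_sims=50, seed=0) == 1.0

    def test_tiled_b_regions_always_pair(self):
        ra = [_region("1", 5_000_000)]
        rb = [_region("1", p) for p in range(100_000, 10_000_000, 200_000)]
        assert count_close_pairs(ra, rb) >= 1
        terr = {"1": (1, 10_000_000)}  # B regions tile this whole territory
        assert reshuffle_empirical_p(ra, rb, terr, n_sims=100, seed=0) == 1.0

    def test_oversized_region_fatal(self):
        ra = [_region("1", 5_000_000, start=1, end=20_000_000)]
        rb = [_region("1", 5_000_000)]
        with pytest.raises(ValueError):
            reshuffle_empirical_p(ra, rb, self.TERR, n_sims=10, seed=0)

    def test_territory_extents(self):
        table = make_table(variant_id=["a", "b", "c"], chrom=["1", "1", "2"],
                           pos=[100, 900, 50])
        terr = territory_from_positions(table.df)
        assert terr == {"1": (100, 900), "2": (50, 50)}

    def test_deterministic_under_seed(self):
        ra = [_region("1", 2_000_000), _region("2", 3_000_000)]
        rb = [_region("1", 2_100_000), _region("2", 8_000_000)]
        p1 = reshuffle_empirical_p(ra, rb, self.TERR, n_sims=200, seed=4)
        p2 = reshuffle_empirical_p(ra, rb, self.TERR, n_sims=200, seed=4)
        assert p1 == p2
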