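"""Pairwise LD statistics and windowed pruning."""

import numpy as np
import pytest

from conftest import make_reference, make_table
from crosscoloc import ld_prune, pairwise_dprime, pairwise_r2
from crosscoloc.ld import LDError, LDReference


def _ref(ids, genotypes, positions=None):
    g = np.asarray(genotypes, dtype=float)
    pos = positions if positions is not None else list(range(1, g.shape[1] + 1))
    return LDReference(list(ids), np.asarray(pos), g)


class TestR2:
    def test_identical_columns(self, rng):
        x = rng.integers(0, 3, 50).astype(float)
        ref = _ref(["a", "b"], np.column_stack([x, x]))
        assert pairwise_r2(ref, "a", "b") == pytest.approx(1.0)

    def test_orthogonal_columns(self):
        x = np.array([0, 0, 2, 2], dtype=float)
        y = np.array([0, 2, 0, 2], dtype=float)
        ref = _ref(["a", "b"], np.column_stack([x, y]))
        assert pairwise_r2(ref, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_pearson(self, rng):
        x = rng.integers(0, 3, 200).astype(float)
        y = np.clip(x + rng.integers(-1, 2, 200), 0, 2).astype(float)
        ref = _ref(["a", "b"], np.column_stack([x, y]))
        # independent oracle: covariance arithmetic written out long-hand
        mx, my = x.mean(), y.mean()
        r = ((x - mx) * (y - my)).sum() / np.sqrt(
            ((x - mx) ** 2).sum() * ((y - my) ** 2).sum()
        )
        assert pairwise_r2(ref, "a", "b") == pytest.approx(r**2, abs=1e-12)

    def test_zero_variance_is_error(self):
        ref = _ref(["a", "b"], np.column_stack([np.ones(10), np.arange(10) % 3]))
        with pytest.raises(LDError, match="a"):
            pairwise_r2(ref, "a", "b")

    def test_symmetry(self, rng):
        g = rng.integers(0, 3, size=(80, 2)).astype(float)
        ref = _ref(["a", "b"], g)
        assert pairwise_r2(ref, "a", "b") == pytest.approx(pairwise_r2(ref, "b", "a"))


def _diplotypes(hap_counts):
    """Genotype columns from explicit haplotype pairs (no phase ambiguity:
    each individual carries two copies of the same haplotype)."""
    x, y = [], []
    for (ha, hb), n in hap_counts.items():
        for _ in range(n):
            x.append(2 * ha)
            y.append(2 * hb)
    return np.column_stack([x, y]).astype(float)


class TestDPrime:
    def test_perfect_coupling(self):
        g = _diplotypes({(1, 1): 25, (0, 0): 25})
        ref = _ref(["a", "b"], g)
        assert pairwise_dprime(ref, "a", "b") == pytest.approx(1.0, abs=1e-9)

    def test_toy_haplotype_table(self):
        # haplotype counts AB=40, Ab=10, aB=10, ab=40 (as 50 homozygous pairs)
        g = _diplotypes({(1, 1): 20, (1, 0): 5, (0, 1): 5, (0, 0): 20})
        ref = _ref(["a", "b"], g)
        # arithmetic oracle: pAB=0.4, pA=pB=0.5 -> D=0.15, Dmax=0.25
        assert pairwise_dprime(ref, "a", "b") == pytest.approx(0.15 / 0.25, abs=1e-6)

    def test_independent_variants_near_zero(self, rng):
        n = 10_000
        hap1 = rng.random((n, 2)) < 0.4
        hap2 = rng.random((n, 2)) < 0.4
        g = np.column_stack([hap1.sum(axis=1), hap2.sum(axis=1)]).astype(float)
        ref = _ref(["a", "b"], g)
        assert pairwise_dprime(ref, "a", "b") < 0.1

    def test_monomorphic_is_error(self):
        ref = _ref(["a", "b"], np.column_stack([np.zeros(10), np.arange(10) % 3]))
        with pytest.raises(LDError):
            pairwise_dprime(ref, "a", "b")

    def test_em_handles_double_heterozygotes(self):
        # coupled haplotypes AB/ab drawn as het pairs -> all (1,1) genotypes
        # plus homozygous anchors resolving the phase
        g = np.vstack(
            [
                _diplotypes({(1, 1): 20, (0, 0): 20}),
                np.tile([1.0, 1.0], (10, 1)),
            ]
        )
        ref = _ref(["a", "b"], g)
        assert pairwise_dprime(ref, "a", "b") == pytest.approx(1.0, abs=1e-6)


class TestPrune:
    def _corr_pair(self, rng, r):
        # dosage pair with sample correlation close to r via duplication+noise
        n = 400
        x = rng.integers(0, 3, n).astype(float)
        flip = rng.random(n) > r
        y = np.where(flip, rng.integers(0, 3, n), x).astype(float)
        return x, y

    def test_close_correlated_pair_pruned_to_one(self, rng):
        x, y = self._corr_pair(rng, 0.8)
        table = make_table(variant_id=["v1", "v2"], pos=[1000, 2000], maf=[0.3, 0.2])
        ref = make_reference(table, np.column_stack([x, y]))
        assert pairwise_r2(ref, "v1", "v2") >= 0.2
        pruned = ld_prune(table, ref)
        assert len(pruned) == 1
        # v2 has the smaller MAF and is removed
        assert pruned.variant_ids == ["v1"]

    def test_distant_pair_untouched(self, rng):
        x, y = self._corr_pair(rng, 0.95)
        table = make_table(variant_id=["v1", "v2"], pos=[1000, 601_000])
        ref = make_reference(table, np.column_stack([x, y]))
        assert pairwise_r2(ref, "v1", "v2") >= 0.2
        pruned = ld_prune(table, ref)
        assert len(pruned) == 2

    def test_exchangeable_block_keeps_one(self, rng):
        # 50 SNPs sharing one latent factor: every pairwise r2 above threshold
        n, m = 2000, 50
        shared = rng.standard_normal(n)
        g = np.empty((n, m))
        for j in range(m):
            g[:, j] = np.round(
                np.clip(0.9 * shared + 0.45 * rng.standard_normal(n) + 1, 0, 2)
            )
        table = make_table(variant_id=[f"v{j}" for j in range(m)],
                           pos=[1000 * (j + 1) for j in range(m)])
        ref = make_reference(table, g)
        # brute-force certificate that the block is exchangeable-high-LD
        for i in range(0, m, 7):
            for j in range(i + 1, m, 11):
                assert pairwise_r2(ref, f"v{i}", f"v{j}") >= 0.2
        pruned = ld_prune(table, ref)
        assert len(pruned) == 1

    def test_missing_variant_fatal(self, rng):
        table = make_table(variant_id=["v1", "v2"], pos=[1, 2])
        ref = _ref(["v1"], rng.integers(0, 3, (50, 1)).astype(float))
        with pytest.raises(LDError, match="v2"):
            ld_prune(table, ref)

    def test_deterministic(self, rng):
        from crosscoloc.simulate import BlockSpec, ScenarioSpec, simulate_pair

        sc = ScenarioSpec(blocks=[BlockSpec(60, 0.9)], n_samples_ref=200, seed=5)
        a, _, ref, _ = simulate_pair(sc)
        p1 = ld_prune(a, ref)
        p2 = ld_prune(a, ref)
        assert p1.variant_ids == p2.variant_ids

    def test_certificate_on_synthetic_genome(self):
        from crosscoloc.simulate import BlockSpec, ScenarioSpec, simulate_pair

        blocks = [BlockSpec(40, rho, chrom="1", start_bp=1 + k * 250_000)
                  for k, rho in enumerate([0.0, 0.5, 0.9, 0.95])]
        sc = ScenarioSpec(blocks=blocks, n_samples_ref=300, seed=11)
        a, _, ref, _ = simulate_pair(sc)
        pruned = ld_prune(a, ref)
        kept = pruned.variant_ids
        pos = dict(zip(a.df["variant_id"], a.df["pos"]))
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                if abs(pos[kept[i]] - pos[kept[j]]) <= 500_000:
                    assert pairwise_r2(ref, kept[i], kept[j]) < 0.2
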