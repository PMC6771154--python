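"""Synthetic paired-trait GWAS summary statistics with known ground truth.

Z-scores are drawn directly from the multivariate-normal summary-statistics
model: within an LD block with correlation matrix ``R``, the vector of
observed z-scores for trait ``t`` is ``z_t = R @ lam_t + eps_t`` with
``eps_t ~ MVN(0, R)`` and ``lam_t`` the vector of non-centrality parameters
(expected z at causal variants, zero elsewhere).  This gives exact control
over planted architectures — a shared causal variant (same or opposite
sign), distinct nearby causals, single-trait signals, or pure null — without
simulating individual-level phenotypes.

A matching genotype reference panel is drawn from the same ``R`` through a
Gaussian copula: two latent haplotypes per sample are thresholded at the
allele-frequency quantile and summed into dosages, so sample LD in the panel
approximates the block correlation used for the z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDReference
from .sumstats import SumStatsTable, TINY_P


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: ``n_snps`` variants with AR(1) correlation
    ``rho ** |i - j|``, evenly spaced ``snp_spacing_bp`` apart."""

    n_snps: int
    rho: float
    snp_spacing_bp: int = 5000
    chrom: str = "1"
    start_bp: int = 1

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")

    @property
    def positions(self) -> np.ndarray:
        return self.start_bp + self.snp_spacing_bp * np.arange(self.n_snps)


@dataclass(frozen=True)
class CausalAssignment:
    """Planted causal variant: (block, snp-within-block) with per-trait
    non-centrality (expected z-score; sign carries direction of effect)."""

    block_index: int
    snp_index: int
    ncp_a: float
    ncp_b: float


@dataclass
class ScenarioSpec:
    """Full simulation scenario: block layout, planted causals, panel size."""

    blocks: list[BlockSpec]
    causal_assignments: list[CausalAssignment] = field(default_factory=list)
    n_samples_ref: int = 400
    n_eff: int = 5000  # effective GWAS sample size entering the SE model
    maf_range: tuple[float, float] = (0.05, 0.5)
    info_range: tuple[float, float] = (0.85, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.causal_assignments:
            if not isinstance(c, CausalAssignment):
                raise TypeError("causal_assignments must hold CausalAssignment")
            if not 0 <= c.block_index < len(self.blocks):
                raise ValueError(f"causal block index {c.block_index} out of range")
            if not 0 <= c.snp_index < self.blocks[c.block_index].n_snps:
                raise ValueError(f"causal snp index {c.snp_index} out of range")

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        blocks = [BlockSpec(**b) for b in d["blocks"]]
        causals = [CausalAssignment(*c) if not isinstance(c, dict) else CausalAssignment(**c)
                   for c in d.get("causal_assignments", [])]
        kwargs = {k: d[k] for k in ("n_samples_ref", "n_eff", "seed") if k in d}
        if "maf_range" in d:
            kwargs["maf_range"] = tuple(d["maf_range"])
        if "info_range" in d:
            kwargs["info_range"] = tuple(d["info_range"])
        return cls(blocks=blocks, causal_assignments=causals, **kwargs)


@dataclass
class TruthRecord:
    """Ground truth of a simulated pair: per-variant non-centralities and the
    intended colocalization class of every block.

    Block classes follow the five-hypothesis vocabulary: ``null`` (no causal),
    ``trait_a`` / ``trait_b`` (one trait only), ``distinct`` (both traits,
    different variants), ``shared_same`` / ``shared_opposite`` (both traits,
    same variant, concordant / discordant sign).
    """

    variants: pd.DataFrame = field(repr=False)  # variant_id, chrom, pos, block, ncp_a, ncp_b
    block_classes: list[str] = field(default_factory=list)


def build_ld_matrix(spec: BlockSpec) -> np.ndarray:
    """AR(1) correlation matrix ``R[i, j] = rho ** |i - j|`` (unit diagonal,
    positive definite for any rho in [0, 1))."""
    idx = np.arange(spec.n_snps)
    return spec.rho ** np.abs(idx[:, None] - idx[None, :])


def classify_block(ncp_a: np.ndarray, ncp_b: np.ndarray) -> str:
    """Intended colocalization class of one block from its planted ncp vectors."""
    both = (ncp_a != 0) & (ncp_b != 0)
    if both.any():
        signs = np.sign(ncp_a[both]) * np.sign(ncp_b[both])
        return "shared_same" if (signs > 0).all() else "shared_opposite"
    has_a = (ncp_a != 0).any()
    has_b = (ncp_b != 0).any()
    if has_a and has_b:
        return "distinct"
    if has_a:
        return "trait_a"
    if has_b:
        return "trait_b"
    return "null"


def _block_genotypes(
    rng: np.random.Generator, chol: np.ndarray, maf: np.ndarray, n_samples: int
) -> np.ndarray:
    """Dosages via Gaussian copula: two thresholded latent haplotypes."""
    n_snps = maf.size
    thresh = stats.norm.ppf(maf)
    dosage = np.zeros((n_samples, n_snps))
    for _ in range(2):
        latent = rng.standard_normal((n_samples, n_snps)) @ chol.T
        dosage += latent < thresh
    # monomorphic columns break r2; give them one heterozygote
    const = dosage.min(axis=0) == dosage.max(axis=0)
    if const.any():
        dosage[0, const] = np.where(dosage[0, const] == 0, 1, dosage[0, const] - 1)
    return dosage


def simulate_pair(
    scenario: ScenarioSpec,
) -> tuple[SumStatsTable, SumStatsTable, LDReference, TruthRecord]:
    """Simulate one paired-trait dataset plus a matching reference panel.

    Per variant the summary statistics are assembled backwards from the
    z-score: ``p = 2 * Phi(-|z|)``, ``se = 1 / sqrt(2 * n_eff * maf * (1 - maf))``
    (the standard binary-trait approximation), ``beta = z * se``.  Fully
    deterministic under ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    lam_a = [np.zeros(b.n_snps) for b in scenario.blocks]
    lam_b = [np.zeros(b.n_snps) for b in scenario.blocks]
    for c in scenario.causal_assignments:
        lam_a[c.block_index][c.snp_index] += c.ncp_a
        lam_b[c.block_index][c.snp_index] += c.ncp_b

    rows_a, rows_b, truth_rows = [], [], []
    geno_cols, geno_ids, geno_pos = [], [], []
    block_classes = []
    lo, hi = scenario.maf_range
    ilo, ihi = scenario.info_range

    for bi, block in enumerate(scenario.blocks):
        R = build_ld_matrix(block)
        try:
            chol = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            # AR(1) is PD in exact arithmetic; jitter covers roundoff at rho ~ 1
            chol = np.linalg.cholesky(R + 1e-10 * np.eye(block.n_snps))
        pos = block.positions
        ids = [f"{block.chrom}:{p}" for p in pos]
        maf = rng.uniform(lo, hi, size=block.n_snps)
        info = rng.uniform(ilo, ihi, size=block.n_snps)
        se = 1.0 / np.sqrt(2.0 * scenario.n_eff * maf * (1.0 - maf))

        z = {}
        for trait, lam in (("a", lam_a[bi]), ("b", lam_b[bi])):
            eps = chol @ rng.standard_normal(block.n_snps)
            z[trait] = R @ lam + eps
        geno = _block_genotypes(rng, chol, maf, scenario.n_samples_ref)

        for trait, rows in (("a", rows_a), ("b", rows_b)):
            zt = z[trait]
            p = np.maximum(2.0 * stats.norm.sf(np.abs(zt)), TINY_P)
            rows.append(
                pd.DataFrame(
                    {
                        "variant_id": ids,
                        "chrom": block.chrom,
                        "pos": pos,
                        "effect_allele": "A",
                        "other_allele": "G",
                        "beta": zt * se,
                        "se": se,
                        "pvalue": p,
                        "maf": maf,
                        "info": info,
                    }
                )
            )
        truth_rows.append(
            pd.DataFrame(
                {
                    "variant_id": ids,
                    "chrom": block.chrom,
                    "pos": pos,
                    "block": bi,
                    "ncp_a": lam_a[bi],
                    "ncp_b": lam_b[bi],
                }
            )
        )
        geno_cols.append(geno)
        geno_ids.extend(ids)
        geno_pos.extend(pos.tolist())
        block_classes.append(classify_block(lam_a[bi], lam_b[bi]))

    table_a = SumStatsTable("trait_a", pd.concat(rows_a, ignore_index=True))
    table_b = SumStatsTable("trait_b", pd.concat(rows_b, ignore_index=True))
    ref = LDReference(geno_ids, np.array(geno_pos), np.concatenate(geno_cols, axis=1))
    truth = TruthRecord(pd.concat(truth_rows, ignore_index=True), block_classes)
    return table_a, table_b, ref, truth


def default_genome(
    n_chrom: int = 4,
    blocks_per_chrom: int = 25,
    n_snps: int = 40,
    rho: float = 0.9,
    snp_spacing_bp: int = 5000,
    block_gap_bp: int = 200_000,
) -> list[BlockSpec]:
    """Desk-scale genome layout: 4 chromosomes x 25 blocks x 40 SNPs by
    default (4000 variants), blocks separated well beyond the region-chaining
    gap so planted signals never merge across blocks."""
    blocks = []
    pitch = n_snps * snp_spacing_bp + block_gap_bp
    for c in range(1, n_chrom + 1):
        for b in range(blocks_per_chrom):
            blocks.append(
                BlockSpec(
                    n_snps=n_snps,
                    rho=rho,
                    snp_spacing_bp=snp_spacing_bp,
                    chrom=str(c),
                    start_bp=1 + b * pitch,
                )
            )
    return blocks
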