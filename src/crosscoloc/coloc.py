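"""Five-hypothesis Bayesian colocalization from per-SNP approximate Bayes
factors.

Each variant in a region gets a Wakefield approximate Bayes factor per trait
(association vs. no association, normal effect prior on the log-odds scale).
Assuming at most one causal variant per trait in the region, the evidence is
combined over the five configurations:

* H0 — neither trait associated in the region;
* H1 / H2 — one trait only;
* H3 — both traits, two DIFFERENT causal variants;
* H4 — both traits, the SAME causal variant.

Posterior probabilities weight each hypothesis' summed configurations by the
per-SNP priors ``p1``, ``p2`` (single-trait causal) and ``p12`` (shared
causal), normalized with log-sum-exp for stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .regions import Region
from .sumstats import PairedTable

HYPOTHESES = ("PP0", "PP1", "PP2", "PP3", "PP4")


@dataclass
class ABFVector:
    """Per-variant log approximate Bayes factors for both traits, in one
    fixed variant order."""

    variant_ids: list[str]
    log_abf_a: np.ndarray
    log_abf_b: np.ndarray

    def __post_init__(self) -> None:
        self.log_abf_a = np.asarray(self.log_abf_a, dtype=float)
        self.log_abf_b = np.asarray(self.log_abf_b, dtype=float)
        n = len(self.variant_ids)
        if self.log_abf_a.shape != (n,) or self.log_abf_b.shape != (n,):
            raise ValueError("log ABF vectors must match the variant list")
        if not (np.isfinite(self.log_abf_a).all() and np.isfinite(self.log_abf_b).all()):
            raise ValueError("log ABFs must be finite")

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class ColocResult:
    """Posterior probabilities PP0..PP4 plus the priors that produced them."""

    pp: np.ndarray
    p1: float
    p2: float
    p12: float
    n_snps: int

    def __getitem__(self, name: str) -> float:
        return float(self.pp[HYPOTHESES.index(name)])

    @property
    def best(self) -> str:
        return HYPOTHESES[int(np.argmax(self.pp))]


def wakefield_log_abf(beta, se, prior_sd: float = 0.2):
    """Log approximate Bayes factor for association at one variant.

    With shrinkage ``r = prior_sd^2 / (prior_sd^2 + se^2)`` and ``z = beta/se``:
    ``log ABF = 0.5*log(1 - r) + z^2 * r / 2``.  Accepts scalars or arrays.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be nonnegative")
    r = prior_sd**2 / (prior_sd**2 + se**2)
    z = beta / se
    out = 0.5 * np.log1p(-r) + z**2 * r / 2.0
    return float(out) if out.ndim == 0 else out


def abf_from_paired(
    paired: PairedTable,
    region: Region | None = None,
    margin_bp: int = 50_000,
    prior_sd: float = 0.2,
) -> ABFVector:
    """Wakefield log ABFs for every paired variant (optionally restricted to
    ``region`` plus a flanking margin)."""
    df = paired.df
    if region is not None:
        df = df[
            (df["chrom"] == region.chrom)
            & (df["pos"] >= region.start_bp - margin_bp)
            & (df["pos"] <= region.end_bp + margin_bp)
        ]
    return ABFVector(
        df["variant_id"].tolist(),
        wakefield_log_abf(df["beta_a"].to_numpy(), df["se_a"].to_numpy(), prior_sd),
        wakefield_log_abf(df["beta_b"].to_numpy(), df["se_b"].to_numpy(), prior_sd),
    )


def coloc_posteriors(
    abf: ABFVector, p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Log hypothesis evidences: ``l1 = lse(lA)``, ``l2 = lse(lB)``,
    ``l4 = lse(lA + lB)`` (same variant) and ``l3`` the sum over ordered
    pairs of different variants, computed as ``l1 + l2`` minus the same-variant
    diagonal.  Prior weights enter per configuration, then everything is
    normalized in log space.
    """
    if len(abf) < 2:
        raise ValueError("colocalization needs at least 2 variants (H3 undefined)")
    la, lb = abf.log_abf_a, abf.log_abf_b
    l1 = logsumexp(la)
    l2 = logsumexp(lb)
    l4 = logsumexp(la + lb)
    # sum over i != j: exp(l1 + l2) - exp(l4), in log space
    diag_frac = np.exp(l4 - (l1 + l2))
    l3 = l1 + l2 + np.log1p(-min(diag_frac, 1.0 - 1e-15))
    logw = np.array(
        [
            0.0,
            np.log(p1) + l1,
            np.log(p2) + l2,
            np.log(p1) + np.log(p2) + l3,
            np.log(p12) + l4,
        ]
    )
    pp = np.exp(logw - logsumexp(logw))
    pp /= pp.sum()
    return ColocResult(pp, p1, p2, p12, len(abf))


def coloc_region_pair(
    paired: PairedTable,
    region_a: Region,
    region_b: Region,
    margin_bp: int = 50_000,
    prior_sd: float = 0.2,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Colocalize the union span of two paired regions plus a margin."""
    if region_a.chrom != region_b.chrom:
        raise ValueError("regions must share a chromosome")
    union = Region(
        chrom=region_a.chrom,
        start_bp=min(region_a.start_bp, region_b.start_bp),
        end_bp=max(region_a.end_bp, region_b.end_bp),
        member_ids=[],
        lead_id=region_a.lead_id,
        lead_pos=region_a.lead_pos,
        lead_p=region_a.lead_p,
        trait="both",
    )
    abf = abf_from_paired(paired, union, margin_bp=margin_bp, prior_sd=prior_sd)
    return coloc_posteriors(abf, p1=p1, p2=p2, p12=p12)
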