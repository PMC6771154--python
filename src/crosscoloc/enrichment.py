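"""Genome-wide shared-association testing on LD-pruned SNPs.

For a pair of traits and a p-value cutoff ``t``, the pruned variants are
cross-tabulated into a 2x2 table — below ``t`` in both traits (``a``), in one
trait only (``b``, ``c``), in neither (``d``) — and enrichment of the
both-low cell is scored with a one-sided Fisher exact test.  A permutation
null (trait B's p-values reshuffled across the pruned SNPs) gives an
empirical p-value that is free of the Fisher test's independence assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ld import PrunedSet
from .sumstats import PairedTable

#: The report's p-value cutoffs, ordered ascending.
THRESHOLDS = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05)


@dataclass
class CrossTab:
    """2x2 cross-tabulation of pruned SNPs at one p-value cutoff."""

    threshold: float
    a: int  # p < t in both traits
    b: int  # p < t in trait A only
    c: int  # p < t in trait B only
    d: int  # neither
    fisher_p: float = float("nan")
    odds_ratio: float = float("nan")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def crosstab(paired: PairedTable, pruned: PrunedSet, t: float) -> CrossTab:
    """Count pruned variants above/below cutoff ``t`` in each trait
    (strict ``p < t``), then attach the Fisher p and odds ratio."""
    if len(pruned) == 0:
        raise ValueError("pruned set is empty")
    df = paired.df[paired.df["variant_id"].isin(set(pruned.variant_ids))]
    low_a = (df["p_a"] < t).to_numpy()
    low_b = (df["p_b"] < t).to_numpy()
    ct = CrossTab(
        threshold=t,
        a=int((low_a & low_b).sum()),
        b=int((low_a & ~low_b).sum()),
        c=int((~low_a & low_b).sum()),
        d=int((~low_a & ~low_b).sum()),
    )
    ct.fisher_p = fisher_one_sided(ct)
    ct.odds_ratio = odds_ratio(ct)
    return ct


def odds_ratio(ct: CrossTab) -> float:
    """Sample odds ratio (a*d)/(b*c); 0 when the numerator vanishes, inf when
    only the denominator does, nan when both do."""
    num = ct.a * ct.d
    den = ct.b * ct.c
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return num / den


def fisher_one_sided(ct) -> float:
    """One-sided Fisher exact p toward enrichment of the both-low cell:
    the hypergeometric tail P(X >= a) given the table margins.

    Accepts a :class:`CrossTab` or a tuple ``(a, b, c, d)``; counts may be
    numpy arrays for a vectorized evaluation.  Tails below 1e-6 are refined
    by summing the log pmf directly over the remaining support, because the
    survival-function shortcut loses all relative accuracy out there.
    """
    if isinstance(ct, CrossTab):
        a, b, c, d = ct.a, ct.b, ct.c, ct.d
    else:
        a, b, c, d = ct
    scalar = np.ndim(a) == 0 and np.ndim(b) == 0 and np.ndim(c) == 0 and np.ndim(d) == 0
    a, b, c, d = np.broadcast_arrays(a, b, c, d)
    total = a + b + c + d
    m1 = a + b
    m2 = a + c
    # X ~ Hypergeom(M=total, n=m1, N=m2); P(X >= a) = sf(a - 1)
    p = np.asarray(stats.hypergeom.sf(a - 1, total, m1, m2), dtype=float)
    p = np.where(total == 0, 1.0, p)  # empty table: P(X >= 0) = 1
    if p.ndim == 0:
        p = p.reshape(1)
        a, m1, m2, total = (x.reshape(1) for x in (a, m1, m2, total))
    idx = np.flatnonzero(p < 1e-6)
    if idx.size:
        aa, mm1, mm2, nn = a.ravel()[idx], m1.ravel()[idx], m2.ravel()[idx], total.ravel()[idx]
        lens = np.minimum(mm1, mm2) - aa + 1
        starts = np.cumsum(lens) - lens
        x = np.arange(int(lens.sum())) - np.repeat(starts, lens) + np.repeat(aa, lens)
        lp = stats.hypergeom.logpmf(x, np.repeat(nn, lens), np.repeat(mm1, lens), np.repeat(mm2, lens))
        peak = np.maximum.reduceat(lp, starts)
        sums = np.add.reduceat(np.exp(lp - np.repeat(peak, lens)), starts)
        p.ravel()[idx] = np.exp(peak) * sums
    p = np.minimum(p, 1.0)
    return float(p[0]) if scalar else p.reshape(np.shape(total))


def permutation_empirical_p(
    paired: PairedTable,
    pruned: PrunedSet,
    t: float,
    n_sims: int = 1000,
    seed: int = 0,
    resample: str = "without",
    add_one: bool = False,
) -> float:
    """Empirical p for the observed both-low count from reassigned trait-B
    p-values.

    Each replicate assigns every pruned SNP a trait-B p-value from the
    observed list — a permutation (``resample='without'``, the default, which
    preserves the marginal p-value set exactly) or a bootstrap draw
    (``resample='with'``) — and recounts SNPs below ``t`` in both traits.
    Returns the proportion of replicates whose count reaches the observed one
    (``add_one=True`` switches to the (b+1)/(n+1) estimator).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if resample not in ("with", "without"):
        raise ValueError("resample must be 'with' or 'without'")
    rng = np.random.default_rng(seed)
    df = paired.df[paired.df["variant_id"].isin(set(pruned.variant_ids))]
    low_a = (df["p_a"] < t).to_numpy()
    low_b = (df["p_b"] < t).to_numpy()
    observed = int((low_a & low_b).sum())
    n = low_b.size

    # Only membership below t matters, so reshuffling the boolean indicator
    # is equivalent to reshuffling the p-values themselves.
    if resample == "without":
        perm = rng.permuted(np.broadcast_to(low_b, (n_sims, n)).copy(), axis=1)
    else:
        perm = low_b[rng.integers(0, n, size=(n_sims, n))]
    counts = (perm & low_a).sum(axis=1)
    hits = int((counts >= observed).sum())
    if add_one:
        return (hits + 1) / (n_sims + 1)
    return hits / n_sims


@dataclass
class EnrichmentReport:
    """Per-threshold cross-tabs and permutation p-values for one trait pair."""

    trait_a: str
    trait_b: str
    rows: list[CrossTab]
    empirical_p: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [r.threshold for r in self.rows],
                "both_low": [r.a for r in self.rows],
                "a_only": [r.b for r in self.rows],
                "b_only": [r.c for r in self.rows],
                "neither": [r.d for r in self.rows],
                "fisher_p": [r.fisher_p for r in self.rows],
                "odds_ratio": [r.odds_ratio for r in self.rows],
                "empirical_p": self.empirical_p,
            }
        )


def enrichment_report(
    paired: PairedTable,
    pruned: PrunedSet,
    n_sims: int = 1000,
    seed: int = 0,
    thresholds: tuple[float, ...] = THRESHOLDS,
) -> EnrichmentReport:
    """Full shared-genetics report over the standard six cutoffs."""
    rows = [crosstab(paired, pruned, t) for t in thresholds]
    emp = [
        permutation_empirical_p(paired, pruned, t, n_sims=n_sims, seed=seed + k)
        for k, t in enumerate(thresholds)
    ]
    return EnrichmentReport(paired.trait_a, paired.trait_b, rows, emp)
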